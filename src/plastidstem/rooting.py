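"""Rooting conventions: outgroup, minimal ancestor deviation (MAD), basal taxon.

Three conventions cover the inputs this package sees:

* ``root_by_outgroup`` — a clearly identified outgroup (typically
  non-cyanobacterial bacteria) defines the root edge;
* ``root_mad`` — minimal-ancestor-deviation rooting for trees without a
  usable outgroup: the root is placed where putative ancestors deviate
  least from the midpoints of all tip pairs;
* ``root_basal_taxon`` — a named basal subgroup (by default *Gloeobacter*)
  is forced to branch first, the convention used for trees containing only
  cyanobacteria and chloroplast sequences.

All three preserve pairwise tip distances exactly; they only choose the
edge and position of the root.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tree_core import PhyloTree, TreeError
from .taxonomy import TaxonMap, AnnotatedTree, annotate

__all__ = [
    "RootCandidate",
    "RootingError",
    "root_by_outgroup",
    "root_mad",
    "root_basal_taxon",
    "root_tree",
]

#: MAD score differences below this are ties, broken by traversal order
MAD_TIE_TOL = 1e-12


class RootingError(TreeError):
    pass


@dataclass(frozen=True)
class RootCandidate:
    """A candidate root position on one edge of the unrooted tree.

    ``edge_tips`` identifies the edge by the tip set on its child side;
    ``x_star`` is the distance of the root from the child end, in branch
    length units; ``mad_score`` is the root-mean-square relative ancestor
    deviation over all tip pairs.
    """

    edge_tips: frozenset[str]
    x_star: float
    mad_score: float


def _resolve_map(tree: PhyloTree, taxa) -> AnnotatedTree:
    if isinstance(taxa, AnnotatedTree):
        return taxa
    return annotate(tree, taxa, allow_unknown=True)


def _root_on_tipset(tree: PhyloTree, target: set[str], warn: list[str] | None = None
                    ) -> PhyloTree:
    """Root at the midpoint of the edge best separating ``target`` tips.

    On the derooted (unrooted) view, pick the edge whose child side equals
    ``target`` if one exists; otherwise the edge maximizing the excess of
    target over non-target tips on one side, recording a warning.
    """
    all_tips = set(tree.tip_labels())
    if not target:
        raise RootingError("no tips of the requested group present")
    if target == all_tips:
        raise RootingError("requested group covers every tip; no root edge exists")
    unrooted = tree.deroot() if len(tree.root.child_nodes()) == 2 else tree.copy()
    best = None  # (score, -size, order, node, side_is_child)
    order = 0
    for node in unrooted.postorder():
        if node.parent_node is None:
            continue
        below = unrooted.leaf_labels_under(node)
        for side in (below, all_tips - below):
            score = len(side & target) - len(side - target)
            key = (score, -len(side), -order)
            if best is None or key > best[0]:
                best = (key, node, side)
        order += 1
    _, node, side = best
    exact = side == target
    if not exact and warn is not None:
        warn.append(
            "outgroup not monophyletic on the unrooted tree; rooting on the edge "
            f"with best separation ({len(side & target)}/{len(target)} tips)"
        )
    return unrooted.reroot(node, 0.5)


def root_by_outgroup(tree: PhyloTree, taxa, outgroup_group: str) -> PhyloTree:
    """Root between the outgroup tips and everything else, at the edge midpoint."""
    atree = _resolve_map(tree, taxa)
    target = atree.tips_in_group(outgroup_group)
    if not target:
        raise RootingError(f"no tips of outgroup group {outgroup_group!r} present")
    warnings: list[str] = []
    rooted = _root_on_tipset(tree, target, warnings)
    rooted.warnings.extend(warnings)
    return rooted


def root_basal_taxon(tree: PhyloTree, taxa, basal_subgroup: str = "gloeobacter") -> PhyloTree:
    """Root so the named basal subgroup branches first (Gloeobacter-first)."""
    atree = _resolve_map(tree, taxa)
    target = atree.tips_in_subgroup(basal_subgroup)
    if not target:
        raise RootingError(
            f"no tips of basal subgroup {basal_subgroup!r}; fall back to root_mad"
        )
    warnings: list[str] = []
    rooted = _root_on_tipset(tree, target, warnings)
    rooted.warnings.extend(warnings)
    return rooted


# -- minimal ancestor deviation -------------------------------------------

def _node_tip_distances(tree: PhyloTree):
    """Distance from every node to every tip, via undirected traversal."""
    nodes = list(tree.nodes())
    index = {id(n): i for i, n in enumerate(nodes)}
    tips = [n for n in nodes if n.is_leaf()]
    tip_index = {id(t): j for j, t in enumerate(tips)}
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(len(nodes))}
    for node in nodes:
        parent = node.parent_node
        if parent is None:
            continue
        i, j, w = index[id(node)], index[id(parent)], float(node.edge.length)
        adj[i].append((j, w))
        adj[j].append((i, w))
    dist = np.zeros((len(nodes), len(tips)))
    for t in tips:
        start = index[id(t)]
        col = tip_index[id(t)]
        seen = {start}
        stack = [(start, 0.0)]
        while stack:
            cur, d = stack.pop()
            dist[cur, col] = d
            for nxt, w in adj[cur]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, d + w))
    return nodes, index, tips, dist


def mad_candidates(tree: PhyloTree) -> list[RootCandidate]:
    """Score every edge of the unrooted tree under the MAD criterion.

    For a candidate root at distance ``x`` from the child end ``i`` of an
    edge, each tip pair (b, c) whose path crosses the root contributes the
    relative deviation ``r = |2 (d_ib + x) / d_bc - 1|``; pairs on one side
    keep their ordinary common ancestor and contribute a position-free
    deviation.  The per-edge optimum has the closed form
    ``x* = sum(d_bc^-2 (d_bc - 2 d_ib)) / (2 sum(d_bc^-2))`` over crossing
    pairs, clamped to the edge.  The score is the RMS deviation over all
    pairs; candidates are returned in deterministic post-order.
    """
    work = tree.deroot() if len(tree.root.child_nodes()) == 2 else tree.copy()
    tips = work.tips()
    if len(tips) < 3:
        raise RootingError("MAD rooting needs at least 3 tips")
    nodes, index, tip_nodes, nd = _node_tip_distances(work)
    tip_pos = {id(t): j for j, t in enumerate(tip_nodes)}
    ntips = len(tip_nodes)
    D = nd[[index[id(t)] for t in tip_nodes], :]  # tip x tip distances
    off = ~np.eye(ntips, dtype=bool)
    if np.any(D[off] <= 0):
        raise RootingError("zero patristic distance between two tips; MAD undefined")
    iu, ju = np.triu_indices(ntips, k=1)
    candidates = []
    for node in work.postorder():
        if node.parent_node is None:
            continue
        length = float(node.edge.length)
        below = np.zeros(ntips, dtype=bool)
        for t in node.leaf_iter():
            below[tip_pos[id(t)]] = True
        if below.all():
            continue
        d_i = nd[index[id(node)], :]  # child end to every tip
        cross = below[iu] != below[ju]
        # orient crossing pairs so b is on the child side
        b = np.where(below[iu[cross]], iu[cross], ju[cross])
        c = np.where(below[iu[cross]], ju[cross], iu[cross])
        dbc = D[b, c]
        dib = d_i[b]
        w = dbc ** -2.0
        x = float(np.sum(w * (dbc - 2.0 * dib)) / (2.0 * np.sum(w)))
        x = min(max(x, 0.0), length)
        r2_cross = (2.0 * (dib + x) / dbc - 1.0) ** 2
        nb, nc = iu[~cross], ju[~cross]
        anc = 0.5 * (d_i[nb] + D[nb, nc] - d_i[nc])
        r2_same = (2.0 * anc / D[nb, nc] - 1.0) ** 2
        score = float(np.sqrt((np.sum(r2_cross) + np.sum(r2_same)) / len(iu)))
        candidates.append(
            RootCandidate(frozenset(work.leaf_labels_under(node)), x, score)
        )
    return candidates


def root_mad(tree: PhyloTree) -> tuple[PhyloTree, RootCandidate]:
    """Return the tree rooted at the global MAD optimum and the candidate."""
    candidates = mad_candidates(tree)
    best = candidates[0]
    for cand in candidates[1:]:
        if cand.mad_score < best.mad_score - MAD_TIE_TOL:
            best = cand
    work = tree.deroot() if len(tree.root.child_nodes()) == 2 else tree.copy()
    for node in work.postorder():
        if node.parent_node is None:
            continue
        if frozenset(work.leaf_labels_under(node)) == best.edge_tips:
            length = float(node.edge.length)
            position = best.x_star / length if length > 0 else 0.0
            return work.reroot(node, position), best
    raise RootingError("MAD root edge not found")  # pragma: no cover


def root_tree(tree: PhyloTree, taxa, directive: str) -> PhyloTree:
    """Apply a rooting directive: ``outgroup:<group>``, ``mad``, ``basal:<subgroup>``."""
    if directive == "mad":
        rooted, _ = root_mad(tree)
        return rooted
    kind, _, arg = directive.partition(":")
    if kind == "outgroup" and arg:
        return root_by_outgroup(tree, taxa, arg)
    if kind == "basal":
        return root_basal_taxon(tree, taxa, arg or "gloeobacter")
    raise RootingError(f"unknown rooting directive {directive!r}")
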