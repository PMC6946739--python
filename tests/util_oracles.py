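"""Independent brute-force oracles and random-input generators for tests.

Everything here deliberately avoids the package's own primitives where it
can: tree parsing for oracles goes straight through dendropy, distances
come from its patristic distance matrix, and the MAD oracle is a plain
grid search over root positions.
"""

import itertools
import random

import dendropy
import numpy as np


def random_newick(rng: random.Random, ntips: int) -> str:
    """Random binary topology with positive lengths, as a Newick string."""
    parts = [f"t{i}" for i in range(ntips)]
    while len(parts) > 1:
        i, j = sorted(rng.sample(range(len(parts)), 2), reverse=True)
        a, b = parts.pop(i), parts.pop(j)
        la = round(rng.uniform(0.05, 2.0), 6)
        lb = round(rng.uniform(0.05, 2.0), 6)
        parts = parts + [f"({a}:{la},{b}:{lb})"]
    return parts[0] + ";"


def dendropy_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )


def mrca_leafset_oracle(newick: str, labels) -> set[str]:
    """Leaf set of the smallest clade containing all ``labels``."""
    tree = dendropy_tree(newick)
    target = set(labels)
    best = None
    for node in tree.preorder_node_iter():
        leafset = {l.taxon.label for l in node.leaf_iter()}
        if target <= leafset and (best is None or len(leafset) < len(best)):
            best = leafset
    return best


def patristic_oracle(newick: str) -> dict[tuple[str, str], float]:
    """All pairwise tip distances via dendropy's distance matrix."""
    tree = dendropy_tree(newick)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    out = {}
    for a, b in itertools.combinations(taxa, 2):
        d = pdm.patristic_distance(a, b)
        out[(a.label, b.label)] = d
        out[(b.label, a.label)] = d
    return out


def mad_grid_oracle(newick: str, npos: int = 10_000) -> float:
    """Minimum RMS relative ancestor deviation by grid search.

    Every edge of the unrooted tree is scanned at ``npos`` equally spaced
    root positions; for each position, pairs split by the root contribute
    ``|2 (d_ib + x) / d_bc - 1|`` and same-side pairs their fixed deviation
    at their ordinary ancestor.
    """
    tree = dendropy_tree(newick)
    tree.deroot()
    tips = list(tree.leaf_node_iter())
    labels = [t.taxon.label for t in tips]
    n = len(tips)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.taxon.label: t.taxon for t in tips}
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])

    # distance from every node to every tip by undirected traversal
    nodes = list(tree.preorder_node_iter())
    index = {id(nd): k for k, nd in enumerate(nodes)}
    adj = {k: [] for k in range(len(nodes))}
    for nd in nodes:
        if nd.parent_node is None:
            continue
        a, b, w = index[id(nd)], index[id(nd.parent_node)], float(nd.edge.length)
        adj[a].append((b, w))
        adj[b].append((a, w))
    tip_cols = {labels[i]: i for i in range(n)}
    nd_dist = np.zeros((len(nodes), n))
    for t in tips:
        start, col = index[id(t)], tip_cols[t.taxon.label]
        seen, stack = {start}, [(start, 0.0)]
        while stack:
            cur, d = stack.pop()
            nd_dist[cur, col] = d
            for nxt, w in adj[cur]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, d + w))

    best = np.inf
    pairs = list(itertools.combinations(range(n), 2))
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        length = float(nd.edge.length)
        below = {l.taxon.label for l in nd.leaf_iter()}
        mask = np.array([lbl in below for lbl in labels])
        d_i = nd_dist[index[id(nd)], :]
        xs = np.linspace(0.0, length, npos)
        total = np.zeros(npos)
        for i, j in pairs:
            if mask[i] != mask[j]:
                b, c = (i, j) if mask[i] else (j, i)
                total += (2.0 * (d_i[b] + xs) / D[b, c] - 1.0) ** 2
            else:
                anc = 0.5 * (d_i[i] + D[i, j] - d_i[j])
                total += (2.0 * anc / D[i, j] - 1.0) ** 2
        best = min(best, float(np.sqrt(total.min() / len(pairs))))
    return best
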