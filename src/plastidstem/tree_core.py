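"""Phylogenetic tree data model and Newick I/O.

The :class:`PhyloTree` wraps a :class:`dendropy.Tree` and exposes the small
set of primitives the rest of the package needs: tip lookup, most recent
common ancestors, patristic path lengths, and rerooting on an arbitrary
edge.  Branch lengths are in substitutions per site throughout; a missing
length in the input is recorded as ``0`` and reported in ``tree.warnings``
rather than raised, so hand-written toy trees remain usable.

Edges are identified by their child node (the node below the edge), which
is unambiguous on a rooted representation.  Numeric internal-node labels
(bootstrap proportions, posterior probabilities) are retained as plain node
labels and never interpreted as taxa.
"""

from __future__ import annotations

import io
from typing import Iterable, Iterator, Sequence

import dendropy

__all__ = [
    "PhyloTree",
    "NewickParseError",
    "DuplicateLabelError",
    "TreeError",
    "parse_newick",
    "write_newick",
    "mrca",
    "path_length",
    "reroot",
]

#: absolute tolerance used for branch-length comparisons package-wide
LENGTH_ATOL = 1e-9


class TreeError(ValueError):
    """Structural misuse of a tree (unknown node, unrooted where rooted needed...)."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


class DuplicateLabelError(NewickParseError):
    """Two tips share a label."""


class PhyloTree:
    """Rooted (or explicitly unrooted) tree with branch lengths.

    Parameters
    ----------
    dtree
        The underlying dendropy tree.  Non-root edges with ``None`` length
        are set to 0 and a warning is recorded.
    rooted
        Whether the outermost node is to be read as a true root.  Most
        operations (``mrca``, clade extraction) require a rooted tree.
    """

    def __init__(self, dtree: dendropy.Tree, rooted: bool = True,
                 warnings: list[str] | None = None):
        self._dt = dtree
        self.rooted = bool(rooted)
        self.warnings: list[str] = list(warnings or [])
        self._normalize()

    # -- construction ----------------------------------------------------

    def _normalize(self) -> None:
        seen: set[str] = set()
        for leaf in self._dt.leaf_node_iter():
            label = self._tip_label(leaf)
            if label is None or label == "":
                raise NewickParseError("tree contains an unlabeled tip")
            if label in seen:
                raise DuplicateLabelError(f"duplicate tip label: {label!r}")
            seen.add(label)
        for node in self._dt.preorder_node_iter():
            if node is self._dt.seed_node:
                continue
            if node.edge.length is None:
                node.edge.length = 0.0
                self.warnings.append(
                    f"missing branch length above {self._describe(node)}; recorded as 0"
                )
            elif node.edge.length < 0:
                raise TreeError(
                    f"negative branch length {node.edge.length} above {self._describe(node)}"
                )

    @staticmethod
    def _tip_label(node) -> str | None:
        if node.taxon is not None:
            return node.taxon.label
        return node.label

    def _describe(self, node) -> str:
        if node.is_leaf():
            return f"tip {self._tip_label(node)!r}"
        return "internal node {" + ",".join(sorted(self.leaf_labels_under(node))[:3]) + ",...}"

    @classmethod
    def from_newick(cls, text: str, rooted: bool = True) -> "PhyloTree":
        if not text.strip().endswith(";"):
            raise NewickParseError(
                f"missing terminal semicolon at character {len(text.rstrip())}"
            )
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except dendropy.utility.error.DataParseError as exc:
            msg = str(exc)
            if "Duplicate taxon labels" in msg:
                label = msg.rsplit(":", 1)[-1].strip()
                raise DuplicateLabelError(f"duplicate tip label: {label!r}") from exc
            raise NewickParseError(msg) from exc
        if "[&U]" in text:
            rooted = False
        return cls(dtree, rooted=rooted)

    def to_newick(self) -> str:
        """Canonical Newick string: stored child order, 17 significant digits."""
        out = self._dt.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".17g",
            unquoted_underscores=True,
        )
        return out.strip() + "\n"

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            dendropy.Tree(self._dt), rooted=self.rooted, warnings=self.warnings
        )

    # -- basic accessors -------------------------------------------------

    @property
    def root(self):
        return self._dt.seed_node

    def nodes(self) -> Iterator:
        return self._dt.preorder_node_iter()

    def postorder(self) -> Iterator:
        return self._dt.postorder_node_iter()

    def tips(self) -> list:
        return list(self._dt.leaf_node_iter())

    def tip_labels(self) -> list[str]:
        return [self._tip_label(t) for t in self.tips()]

    def tip(self, label: str):
        for t in self._dt.leaf_node_iter():
            if self._tip_label(t) == label:
                return t
        raise TreeError(f"unknown tip label: {label!r}")

    def label_of(self, node) -> str | None:
        return self._tip_label(node)

    def leaf_labels_under(self, node) -> set[str]:
        return {self._tip_label(t) for t in node.leaf_iter()}

    def edges(self) -> list:
        """Non-root nodes, each standing for the edge above it."""
        return [n for n in self._dt.preorder_node_iter() if n.parent_node is not None]

    def branch_length(self, node) -> float:
        if node.parent_node is None:
            return 0.0
        return float(node.edge.length)

    def scale(self, factor: float) -> "PhyloTree":
        """Return a copy with every branch length multiplied by ``factor``."""
        out = self.copy()
        for node in out._dt.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = node.edge.length * factor
        return out

    # -- ancestry and distances ------------------------------------------

    def _require_node(self, node) -> None:
        # membership check by identity walk to the seed node
        probe = node
        while probe.parent_node is not None:
            probe = probe.parent_node
        if probe is not self._dt.seed_node:
            raise TreeError("node does not belong to this tree")

    def root_path(self, node) -> list:
        """Nodes from ``node`` up to and including the root."""
        path = [node]
        while path[-1].parent_node is not None:
            path.append(path[-1].parent_node)
        return path

    def mrca(self, labels: Iterable[str]):
        if not self.rooted:
            raise TreeError("mrca requires a rooted tree")
        labels = list(labels)
        if not labels:
            raise TreeError("mrca of an empty label set")
        nodes = [self.tip(label) for label in labels]
        return self.mrca_nodes(nodes)

    def mrca_nodes(self, nodes: Sequence):
        common = None
        for node in nodes:
            anc = set(id(n) for n in self.root_path(node))
            common = anc if common is None else (common & anc)
        # deepest node in the common ancestor set
        for candidate in self.root_path(nodes[0]):
            if id(candidate) in common:
                return candidate
        raise TreeError("nodes share no common ancestor")  # pragma: no cover

    def path_length(self, a, b) -> float:
        """Sum of branch lengths on the unique path between two nodes."""
        self._require_node(a)
        self._require_node(b)
        if a is b:
            return 0.0
        anc = self.mrca_nodes([a, b])
        total = 0.0
        for node in (a, b):
            probe = node
            while probe is not anc:
                total += probe.edge.length
                probe = probe.parent_node
        return float(total)

    def depth(self, node) -> float:
        """Branch-length distance from the root."""
        total = 0.0
        probe = node
        while probe.parent_node is not None:
            total += probe.edge.length
            probe = probe.parent_node
        return float(total)

    def tip_distance_matrix(self) -> tuple[list[str], "np.ndarray"]:
        """Labels and the dense patristic distance matrix between all tips."""
        import numpy as np

        tips = self.tips()
        labels = [self._tip_label(t) for t in tips]
        depths = {id(t): self.depth(t) for t in self.nodes()}
        n = len(tips)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                anc = self.mrca_nodes([tips[i], tips[j]])
                d = depths[id(tips[i])] + depths[id(tips[j])] - 2 * depths[id(anc)]
                mat[i, j] = mat[j, i] = d
        return labels, mat

    # -- rerooting --------------------------------------------------------

    def deroot(self) -> "PhyloTree":
        """Collapse a bifurcating root into a trifurcation (unrooted view)."""
        out = self.copy()
        out._dt.deroot()
        out.rooted = False
        return out

    def reroot(self, edge_child, position: float) -> "PhyloTree":
        """Root on the edge above ``edge_child``.

        ``position`` is the fraction of the edge length measured from the
        child end at which the new root is inserted; pairwise tip distances
        are preserved exactly.
        """
        if not (0.0 <= position <= 1.0):
            raise TreeError(f"root position {position} outside [0, 1]")
        self._require_node(edge_child)
        out = self.copy()
        # map the node into the copy by its leaf set
        target_leaves = self.leaf_labels_under(edge_child)
        target = None
        for node in out._dt.preorder_node_iter():
            if node.parent_node is None:
                continue
            if out.leaf_labels_under(node) == target_leaves:
                target = node
                break
        if target is None:  # pragma: no cover
            raise TreeError("edge not found in tree copy")
        length = target.edge.length or 0.0
        out._dt.reroot_at_edge(
            target.edge,
            length1=(1.0 - position) * length,  # tail (old parent) side
            length2=position * length,          # child side
            suppress_unifurcations=True,
        )
        out.rooted = True
        return out


# -- module-level functional surface --------------------------------------

def parse_newick(text: str, rooted: bool = True) -> PhyloTree:
    """Parse a single Newick tree; see :meth:`PhyloTree.from_newick`."""
    return PhyloTree.from_newick(text, rooted=rooted)


def read_newick(path) -> PhyloTree:
    with io.open(path, "r", encoding="utf-8") as fh:
        return parse_newick(fh.read())


def write_newick(tree: PhyloTree) -> str:
    return tree.to_newick()


def mrca(tree: PhyloTree, labels: Iterable[str]):
    return tree.mrca(labels)


def path_length(tree: PhyloTree, a, b) -> float:
    return tree.path_length(a, b)


def reroot(tree: PhyloTree, edge_child, position: float) -> PhyloTree:
    return tree.reroot(edge_child, position)
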