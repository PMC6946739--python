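"""Relative stem lengths: the acquisition-time proxy for chloroplast genes.

For one lineage in one rooted gene tree, the *stem* S runs from the point
where the lineage's clade attaches to the rest of the tree (its origin)
down to the clade's first internal divergence (its crown: the LVCA for
green, the LRCA for red).  The *leaf* L is the median branch length within
the crown clade, normalizing the stem for the gene's evolutionary rate.
The ratio S/L (VS/VL for green, RS/RL for red) is the relative stem
length: under a constant rate it is proportional to the time between gene
acquisition and lineage diversification, so larger values mean earlier
acquisition.  The median branch length of the neighboring cyanobacterial
clade (CL) provides a rate control, reported as CL/L.

Per-protein values from different inference methods (ML, BI) are combined
as geometric means, and a set of canonical genes (chloroplast rRNA,
house-keeping proteins) defines a reference point with log-scale
average +/- SD bands against which earlier/canonical/later acquisition is
called.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Sequence

import numpy as np

from .taxonomy import AnnotatedTree
from .classify import lineage_clade, ClassifyError, _lineage_groups

__all__ = [
    "StemMetrics",
    "CombinedMetrics",
    "ReferencePoint",
    "StemError",
    "stem_and_leaf",
    "cyano_reference",
    "stem_metrics",
    "geometric_mean",
    "combine_methods",
    "reference_point",
    "compare_to_reference",
]

MODES = ("clade_branches", "tip_depth")


class StemError(ValueError):
    pass


@dataclass
class StemMetrics:
    """Stem/leaf measurements for one lineage in one tree."""

    lineage: str
    S: float  # stem length, substitutions/site (VS or RS)
    L: float  # leaf length, substitutions/site (VL or RL)
    CL: float | None  # neighboring-cyanobacteria median branch length
    ratio: float  # S/L, the relative stem length
    cl_ratio: float | None  # CL/L rate control (None when CL missing)
    mode: str = "clade_branches"
    method: str = ""


@dataclass
class CombinedMetrics:
    """Per-protein geometric mean of stem ratios across inference methods."""

    lineage: str
    ratio: float
    cl_ratio: float | None
    methods: list[str]
    per_method: dict[str, StemMetrics]


@dataclass
class ReferencePoint:
    """Canonical acquisition reference with log-scale average +/- SD bands."""

    vs_vl: float | None
    rs_rl: float | None
    cl_vl: float | None
    bands: dict[str, tuple[float, float]]  # axis -> (low, high)


def _clade_origin(atree: AnnotatedTree, lineage: str, crown):
    """Nearest ancestor of the crown with a non-lineage tip outside the crown."""
    tree = atree.tree
    groups = _lineage_groups(lineage)
    crown_tips = tree.leaf_labels_under(crown)
    node = crown
    while node.parent_node is not None:
        parent = node.parent_node
        outside = tree.leaf_labels_under(parent) - crown_tips
        if any(atree.group_of(l) not in groups for l in outside):
            return parent
        node = parent
    return None


def _clade_branch_lengths(tree, crown, drop: set[str] | None = None) -> list[float]:
    """Lengths of all edges strictly inside the crown clade.

    Edges leading only to tips in ``drop`` (and internal edges all of whose
    descendants are dropped) are omitted.
    """
    drop = drop or set()
    lengths = []
    for node in crown.preorder_iter():
        if node is crown:
            continue
        tips = {tree.label_of(t) for t in node.leaf_iter()}
        if tips <= drop:
            continue
        lengths.append(float(node.edge.length))
    return lengths


def _tip_depths(tree, crown, drop: set[str] | None = None) -> list[float]:
    drop = drop or set()
    return [
        tree.path_length(crown, t)
        for t in crown.leaf_iter()
        if tree.label_of(t) not in drop
    ]


def stem_and_leaf(atree: AnnotatedTree, lineage: str, mode: str = "clade_branches",
                  k_intruders: int = 0):
    """Measure the stem S and leaf L for one lineage; returns (S, L, crown).

    ``mode`` selects the leaf-length reading: ``clade_branches`` (default)
    is the median of every branch strictly inside the crown clade;
    ``tip_depth`` is the median crown-to-tip path length.
    """
    if mode not in MODES:
        raise StemError(f"unknown leaf-length mode {mode!r}")
    clade = lineage_clade(atree, lineage, k_intruders)
    if clade.status == "unresolved":
        raise StemError(
            f"{lineage} clade unresolved ({len(clade.intruders)} intruders); "
            "stem not measured"
        )
    atree = clade.atree
    tree = atree.tree
    origin = _clade_origin(atree, lineage, clade.crown)
    if origin is None:
        raise StemError("stem undefined: lineage crown has no external ancestor")
    S = tree.path_length(clade.crown, origin)
    if mode == "clade_branches":
        lengths = _clade_branch_lengths(tree, clade.crown)
    else:
        lengths = _tip_depths(tree, clade.crown)
    if not lengths:
        raise StemError("single-tip clade: leaf length undefined")
    L = float(median(lengths))
    if L <= 0:
        raise StemError("leaf length is zero; relative stem length undefined")
    return S, L, clade.crown


def _largest_cyano_subclade(atree: AnnotatedTree, top):
    """Largest all-cyanobacterial subclade within the subtree at ``top``."""
    tree = atree.tree
    best = None
    best_size = 0
    for node in top.preorder_iter():
        tips = {tree.label_of(t) for t in node.leaf_iter()}
        if all(atree.group_of(l) == "cyanobacteria" for l in tips):
            if len(tips) > best_size:
                best, best_size = node, len(tips)
    return best


def cyano_reference(atree: AnnotatedTree, lineage: str, mode: str = "clade_branches",
                    k_intruders: int = 0) -> float | None:
    """Median branch length CL of the cyanobacterial clade neighboring the stem.

    The neighbor is the largest all-cyanobacterial subclade among the
    sibling subtree(s) of the stem origin.  Tips flagged ``cl_exclude``
    (long-branch marine picocyanobacteria) are dropped first; CL is missing
    (None) when no cyanobacterial neighbor exists or fewer than two
    branches survive exclusion.
    """
    if mode not in MODES:
        raise StemError(f"unknown leaf-length mode {mode!r}")
    clade = lineage_clade(atree, lineage, k_intruders)
    if clade.status == "unresolved":
        return None
    atree = clade.atree
    tree = atree.tree
    origin = _clade_origin(atree, lineage, clade.crown)
    if origin is None or origin.parent_node is None:
        return None
    best = None
    best_size = 0
    for sibling in origin.parent_node.child_nodes():
        if sibling is origin:
            continue
        cand = _largest_cyano_subclade(atree, sibling)
        if cand is not None:
            size = len(list(cand.leaf_iter()))
            if size > best_size:
                best, best_size = cand, size
    if best is None:
        return None
    drop = atree.tips_with_flag("cl_exclude")
    if mode == "clade_branches":
        lengths = _clade_branch_lengths(tree, best, drop)
    else:
        lengths = _tip_depths(tree, best, drop)
    if len(lengths) < 2:
        return None
    return float(median(lengths))


def stem_metrics(atree: AnnotatedTree, lineage: str, mode: str = "clade_branches",
                 method: str = "", k_intruders: int = 0) -> StemMetrics:
    """Full stem/leaf/CL measurement for one lineage of one tree."""
    S, L, _crown = stem_and_leaf(atree, lineage, mode, k_intruders)
    CL = cyano_reference(atree, lineage, mode, k_intruders)
    return StemMetrics(
        lineage=lineage,
        S=S,
        L=L,
        CL=CL,
        ratio=S / L,
        cl_ratio=(CL / L) if CL is not None else None,
        mode=mode,
        method=method,
    )


def geometric_mean(values: Iterable[float]) -> float:
    """exp(mean(log values)); defined only for nonempty positive inputs."""
    vals = [float(v) for v in values]
    if not vals:
        raise StemError("geometric mean of an empty collection")
    if any(v <= 0 for v in vals):
        raise StemError("geometric mean requires strictly positive values")
    return float(math.exp(sum(math.log(v) for v in vals) / len(vals)))


def combine_methods(metrics: Sequence[StemMetrics]) -> CombinedMetrics:
    """Geometric-mean aggregation of one protein/lineage across methods.

    CL/L is combined only over the methods where CL was measurable.
    """
    if not metrics:
        raise StemError("no per-method metrics to combine")
    lineages = {m.lineage for m in metrics}
    if len(lineages) != 1:
        raise StemError(f"cannot combine metrics across lineages {sorted(lineages)}")
    cl_vals = [m.cl_ratio for m in metrics if m.cl_ratio is not None]
    return CombinedMetrics(
        lineage=metrics[0].lineage,
        ratio=geometric_mean([m.ratio for m in metrics]),
        cl_ratio=geometric_mean(cl_vals) if cl_vals else None,
        methods=[m.method for m in metrics],
        per_method={m.method: m for m in metrics},
    )


def _log_band(values: list[float]) -> tuple[float, float, float]:
    logs = np.log(np.asarray(values, dtype=float))
    mean = float(np.mean(logs))
    sd = float(np.std(logs, ddof=1)) if len(logs) > 1 else 0.0
    return math.exp(mean), math.exp(mean - sd), math.exp(mean + sd)


def reference_point(rows: Sequence[tuple]) -> ReferencePoint:
    """Canonical reference from (label, vs_vl, rs_rl, cl_vl) rows.

    Each axis is the geometric mean over rows where the value is present;
    bands are exp(mean +/- SD) of the log values.  An axis with no data is
    missing (None).
    """
    if not rows:
        raise StemError("reference point needs at least one row")
    axes = {"vs_vl": [], "rs_rl": [], "cl_vl": []}
    for row in rows:
        _label, vs, rs, cl = row
        for key, val in (("vs_vl", vs), ("rs_rl", rs), ("cl_vl", cl)):
            if val is not None:
                if val <= 0:
                    raise StemError(f"non-positive {key} value {val} in reference rows")
                axes[key].append(float(val))
    refs: dict[str, float | None] = {}
    bands: dict[str, tuple[float, float]] = {}
    for key, vals in axes.items():
        if vals:
            ref, low, high = _log_band(vals)
            refs[key] = ref
            bands[key] = (low, high)
        else:
            refs[key] = None
    return ReferencePoint(refs["vs_vl"], refs["rs_rl"], refs["cl_vl"], bands)


def compare_to_reference(combined: CombinedMetrics, ref: ReferencePoint) -> dict[str, str]:
    """Timing category per axis: earlier / canonical / later.

    A value above the reference band means the gene was acquired earlier
    than the canonical reference point; below, later; inside, canonical.
    The stem axis is vs_vl for green and rs_rl for red; cl_vl is compared
    when the rate control was measurable.
    """
    stem_axis = "vs_vl" if combined.lineage == "green" else "rs_rl"
    out: dict[str, str] = {}
    for axis, value in ((stem_axis, combined.ratio), ("cl_vl", combined.cl_ratio)):
        if value is None or axis not in ref.bands:
            out[axis] = "missing"
            continue
        low, high = ref.bands[axis]
        if value > high:
            out[axis] = "earlier"
        elif value < low:
            out[axis] = "later"
        else:
            out[axis] = "canonical"
    return out
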