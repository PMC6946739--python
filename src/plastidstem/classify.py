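"""Topology-type classification of rooted, taxonomy-annotated gene trees.

Each tree is classified per lineage (green or red) into one of five origin
types by where the Archaeplastida clade containing the lineage attaches:

* T1 — inside the cyanobacterial clade (cyanobacteria paraphyletic);
* T1c — same pattern, but the tree holds only cyanobacteria and
  Archaeplastida, so no external outgroup can root it and the call relies
  on the basal-taxon or MAD rooting convention;
* T2 — sister to the entire cyanobacterial clade;
* T3 — sister to non-cyanobacterial bacteria;
* T4 — sister to other eukaryotes;
* T5 — the tree contains no chloroplast-lineage tips at all (a purely
  cyanobacterial protein).

For cyanobacteria-derived types the sub-origin records where within
cyanobacteria the attachment lies: the alpha clade, the beta clade, or
deep (basal taxa involved, or alpha and beta mixed in the sister set).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .taxonomy import AnnotatedTree, ARCHAEPLASTIDA, BASAL_CYANO_SUBGROUPS

__all__ = [
    "CladeResult",
    "TreeTypeCall",
    "ClassifyError",
    "lineage_clade",
    "classify_lineage",
    "suborigin",
]

#: default tolerated intruder count inside a lineage clade
DEFAULT_K_INTRUDERS = 0
#: default sister-set purity threshold for T3/T4 calls
DEFAULT_PURITY = 0.8

CYANO_DERIVED_TYPES = frozenset({"T1", "T1c", "T2"})


class ClassifyError(ValueError):
    pass


@dataclass
class CladeResult:
    """The crown clade of one lineage: its node, tips, and contamination."""

    lineage: str
    crown: object  # node in the (rogue-pruned) tree held in ``atree``
    atree: AnnotatedTree
    tips: set[str]
    intruders: set[str]
    status: str  # clean | tolerated | unresolved


@dataclass
class TreeTypeCall:
    lineage: str
    tree_type: str  # T1 | T1c | T2 | T3 | T4 | T5 | unresolved
    sub_origin: str = "none"  # deep | alpha | beta | none
    sister_profile: dict[str, float] = field(default_factory=dict)
    sister_tips: set[str] = field(default_factory=set)
    separated_lineages: bool = False
    status: str = ""
    method: str = ""

    def profile_json(self) -> str:
        return json.dumps(self.sister_profile, sort_keys=True)


def _lineage_groups(lineage: str) -> frozenset[str]:
    if lineage == "archaeplastida":
        return ARCHAEPLASTIDA
    if lineage in ("green", "red"):
        return frozenset({lineage})
    raise ClassifyError(f"unknown lineage {lineage!r}")


def _crown_labels(atree: AnnotatedTree, lineage: str, lineage_tips: set[str]) -> set[str]:
    """Tips whose MRCA defines the crown.

    When both recognized subgroups of a lineage are present the crown is
    their joint MRCA (the LVCA for green, the LRCA for red); otherwise it
    is the MRCA of all lineage tips.
    """
    pairs = {"green": ("chlorophyte", "streptophyte"),
             "red": ("cyanidiophytina", "rhodophytina")}
    if lineage in pairs:
        a, b = pairs[lineage]
        sa = atree.tips_in_subgroup(a) & lineage_tips
        sb = atree.tips_in_subgroup(b) & lineage_tips
        if sa and sb:
            return sa | sb
    return lineage_tips


def lineage_clade(atree: AnnotatedTree, lineage: str,
                  k_intruders: int = DEFAULT_K_INTRUDERS) -> CladeResult:
    """Locate the crown clade of a lineage and count intruding tips.

    Rogue-flagged tips are pruned first.  Status is ``clean`` with no
    intruders, ``tolerated`` with at most ``k_intruders``, ``unresolved``
    beyond that.
    """
    if not atree.tree.rooted:
        raise ClassifyError("lineage_clade requires a rooted tree")
    atree = atree.without_rogues()
    groups = _lineage_groups(lineage)
    lineage_tips = set().union(*(atree.tips_in_group(g) for g in groups))
    if len(lineage_tips) < 2:
        raise ClassifyError(f"lineage absent: fewer than 2 {lineage} tips")
    crown = atree.tree.mrca(_crown_labels(atree, lineage, lineage_tips))
    under = atree.tree.leaf_labels_under(crown)
    intruders = {l for l in under if atree.group_of(l) not in groups}
    if not intruders:
        status = "clean"
    elif len(intruders) <= k_intruders:
        status = "tolerated"
    else:
        status = "unresolved"
    return CladeResult(lineage, crown, atree, under, intruders, status)


def _attachment_sister(atree: AnnotatedTree, crown) -> set[str] | None:
    """Sister tip set at the attachment point of the Archaeplastida complex.

    Ascend from the crown while the newly gained tips are all Archaeplastida
    (the lineage's fellow primary-plastid lineages); stop at the first
    ancestor contributing a non-Archaeplastida tip and return the tips of
    its sibling subtree(s).  None if the crown reaches the root first.
    """
    tree = atree.tree
    node = crown
    while node.parent_node is not None:
        parent = node.parent_node
        gained = tree.leaf_labels_under(parent) - tree.leaf_labels_under(node)
        if any(atree.group_of(l) not in ARCHAEPLASTIDA for l in gained):
            return gained
        node = parent
    return None


def suborigin(atree: AnnotatedTree, call: TreeTypeCall) -> str:
    """Origin within cyanobacteria for a T1/T1c/T2 call: alpha, beta, or deep."""
    if call.tree_type not in CYANO_DERIVED_TYPES:
        raise ClassifyError(f"sub-origin undefined for tree type {call.tree_type}")
    cyano = {l for l in call.sister_tips if atree.records[l].group == "cyanobacteria"}
    subgroups = {atree.records[l].subgroup for l in cyano}
    if subgroups & BASAL_CYANO_SUBGROUPS or {"alpha", "beta"} <= subgroups:
        return "deep"
    if cyano and subgroups == {"alpha"}:
        return "alpha"
    if cyano and subgroups == {"beta"}:
        return "beta"
    return "none"


def classify_lineage(atree: AnnotatedTree, lineage: str,
                     k_intruders: int = DEFAULT_K_INTRUDERS,
                     purity: float = DEFAULT_PURITY,
                     method: str = "") -> TreeTypeCall:
    """Classify one lineage of a rooted, annotated tree into an origin type.

    The sister set is read at the attachment of the whole Archaeplastida
    complex, so a green clade whose immediate sister is the red clade is
    classified by what the combined clade attaches to.  A sister that is
    purely cyanobacterial yields T1 (proper subset of cyanobacteria) or T2
    (all of it); otherwise a fraction of at least ``purity`` of
    ``bacteria_other`` or ``eukaryote_other`` tips yields T3 or T4; anything
    else is unresolved, never forced.
    """
    arch_tips = set().union(*(atree.tips_in_group(g) for g in ARCHAEPLASTIDA))
    if not arch_tips:
        return TreeTypeCall(lineage, "T5", "none", {}, set(), False, "clean", method)
    try:
        clade = lineage_clade(atree, lineage, k_intruders)
    except ClassifyError:
        return TreeTypeCall(lineage, "unresolved", "none", {}, set(), False,
                            "unresolved", method)
    if clade.status == "unresolved":
        return TreeTypeCall(lineage, "unresolved", "none", {}, set(), False,
                            "unresolved", method)
    atree = clade.atree  # rogue-pruned view
    sister = _attachment_sister(atree, clade.crown)
    call = TreeTypeCall(lineage, "unresolved", "none", {}, sister or set(), False,
                        clade.status, method)
    call.separated_lineages = _separated(atree)
    if sister is None:
        return call
    profile: dict[str, float] = {}
    for label in sister:
        g = atree.records[label].group
        profile[g] = profile.get(g, 0.0) + 1.0
    profile = {g: n / len(sister) for g, n in profile.items()}
    call.sister_profile = profile
    cyano_all = atree.tips_in_group("cyanobacteria")
    if profile.get("cyanobacteria", 0.0) == 1.0:
        call.tree_type = "T2" if sister == cyano_all else "T1"
    elif profile.get("bacteria_other", 0.0) >= purity:
        call.tree_type = "T3"
    elif profile.get("eukaryote_other", 0.0) >= purity:
        call.tree_type = "T4"
    if call.tree_type in ("T1", "T2"):
        outside = {
            l for l, r in atree.records.items()
            if r.group not in ARCHAEPLASTIDA and r.group != "cyanobacteria"
        }
        if not outside:
            call.tree_type = "T1c"
    if call.tree_type in CYANO_DERIVED_TYPES:
        call.sub_origin = suborigin(atree, call)
    return call


def _separated(atree: AnnotatedTree) -> bool:
    """True when green and red do not form one Archaeplastida clade together."""
    green = atree.tips_in_group("green")
    red = atree.tips_in_group("red")
    if not green or not red:
        return False
    joint = atree.tree.mrca(green | red)
    under = atree.tree.leaf_labels_under(joint)
    return any(atree.group_of(l) not in ARCHAEPLASTIDA for l in under)
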