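"""Synthetic gene trees with known acquisition structure.

The generator builds an ultrametric time tree for one of the origin-type
archetypes, records the true stem/leaf values on it, then perturbs branch
lengths with independent lognormal rate factors to emulate rate variation
across branches.  Because the truth is measured on the generated time tree
with the same median rules the estimator uses, recovery is exact at
``sigma = 0`` and degrades gracefully as rate noise grows.

Each crown clade is grown as a pure-birth (Yule) tree rescaled to its
configured depth.  The Archaeplastida clade — green (chlorophyte +
streptophyte) and red (Cyanidiophytina + Rhodophytina) joined at the
archaeplastida crown — is attached via a stem of duration ``s`` at a
position determined by the requested tree type: inside the cyanobacterial
radiation next to the alpha clade, the beta clade, or below both (deep)
for T1; sister to all cyanobacteria for T2; sister to the other-bacteria
or other-eukaryote clade for T3/T4.  T1c drops every non-cyanobacterial
outgroup, keeping a Gloeobacter-first basal ladder so the basal-taxon
rooting convention applies; T5 omits the Archaeplastida entirely.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np

from .tree_core import PhyloTree
from .taxonomy import TaxonRecord, TaxonMap, annotate, AnnotatedTree, load_taxon_map
from . import stems as stems_mod

__all__ = ["SimConfig", "SimBundle", "SimulationError", "simulate_tree", "apply_rate_noise"]

TREE_TYPES = ("T1", "T1c", "T2", "T3", "T4", "T5")
SUB_ORIGINS = ("deep", "alpha", "beta")

#: basal cyanobacterial subgroups, deepest-branching first
BASAL_LADDER = ("gloeobacter", "yellowstone", "pseudanabaena")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; times are in arbitrary time units.

    ``s`` is the acquisition-stem duration from the archaeplastida crown to
    the attachment point; ``d_green``/``d_red``/``d_arch`` are crown depths
    of the green, red and combined archaeplastida clades; ``sigma`` is the
    per-branch lognormal rate-noise SD on the log scale.  Clade sizes for
    the green/red lineages are ignored for T5, which has no chloroplast
    tips by definition.
    """

    tree_type: str = "T2"
    sub_origin: str = "deep"
    s: float = 0.5
    d_green: float = 1.0
    d_red: float = 1.0
    d_arch: float = 1.3
    n_chlorophyte: int = 3
    n_streptophyte: int = 3
    n_cyanidiophytina: int = 2
    n_rhodophytina: int = 3
    n_alpha: int = 4
    n_beta: int = 5
    n_basal: int = 3
    n_bact_other: int = 3
    n_euk_other: int = 3
    sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.tree_type not in TREE_TYPES:
            raise SimulationError(f"unknown tree_type {self.tree_type!r}")
        if self.sub_origin not in SUB_ORIGINS:
            raise SimulationError(f"unknown sub_origin {self.sub_origin!r}")
        if self.s < 0 or self.sigma < 0:
            raise SimulationError("s and sigma must be nonnegative")
        for name in ("d_green", "d_red", "d_arch"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        if self.tree_type != "T5":
            if self.d_arch <= max(self.d_green, self.d_red):
                raise SimulationError("d_arch must exceed both lineage crown depths")
            if min(self.n_chlorophyte, self.n_streptophyte) < 1:
                raise SimulationError("green lineage needs both subgroup clades")
            if min(self.n_cyanidiophytina, self.n_rhodophytina) < 1:
                raise SimulationError("red lineage needs both subgroup clades")
        if self.tree_type in ("T1", "T1c"):
            if self.n_basal < 1:
                raise SimulationError("T1/T1c need at least one basal cyanobacterium")
            if self.sub_origin == "alpha" and self.n_alpha < 1:
                raise SimulationError("sub_origin alpha needs alpha tips")
            if self.sub_origin == "beta" and self.n_beta < 1:
                raise SimulationError("sub_origin beta needs beta tips")
            if self.sub_origin == "deep" and min(self.n_alpha, self.n_beta) < 1:
                raise SimulationError("deep sub_origin needs both alpha and beta tips")
        if self.tree_type in ("T2", "T5"):
            if self.n_alpha + self.n_beta + self.n_basal < 1:
                raise SimulationError("cyanobacterial clade is empty")
        if self.tree_type == "T3" and self.n_bact_other < 1:
            raise SimulationError("T3 needs bacteria_other tips")
        if self.tree_type == "T4" and self.n_euk_other < 1:
            raise SimulationError("T4 needs eukaryote_other tips")


@dataclass
class SimBundle:
    """Newick text, taxonomy TSV text, and the generation truth record."""

    newick: str
    taxonomy_tsv: str
    truth: dict
    config: SimConfig = field(repr=False, default=None)

    def tree(self) -> PhyloTree:
        return PhyloTree.from_newick(self.newick)

    def taxon_map(self) -> TaxonMap:
        import io

        return load_taxon_map(io.StringIO(self.taxonomy_tsv))

    def annotated(self) -> AnnotatedTree:
        return annotate(self.tree(), self.taxon_map())

    def write(self, directory) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "trees": directory / "trees.nwk",
            "taxonomy": directory / "taxonomy.tsv",
            "truth": directory / "truth.json",
        }
        paths["trees"].write_text(self.newick)
        paths["taxonomy"].write_text(self.taxonomy_tsv)
        paths["truth"].write_text(json.dumps(self.truth, indent=1, sort_keys=True) + "\n")
        return paths


# -- clade construction ----------------------------------------------------

def _leaf(label: str) -> dendropy.Node:
    node = dendropy.Node()
    node.label = label  # taxa assigned when the full tree is finalized
    node.age_ = 0.0
    return node


def _join(children, age: float) -> dendropy.Node:
    node = dendropy.Node()
    node.age_ = float(age)
    for child in children:
        if child is not None:
            node.add_child(child)
    return node


def _yule_clade(labels: list[str], depth: float, rng: random.Random) -> dendropy.Node:
    """Ultrametric pure-birth clade over ``labels`` with crown age ``depth``."""
    if len(labels) == 1:
        return _leaf(labels[0])
    from dendropy.model import birthdeath

    tree = birthdeath.birth_death_tree(1.0, 0.0, num_extant_tips=len(labels), rng=rng)
    # the process stops exactly at the last split; extend every terminal
    # branch by one more waiting time so no tip edge has zero length
    extra = rng.expovariate(len(labels))
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    tree.calc_node_ages(ultrametricity_precision=False)
    scale = depth / tree.seed_node.age
    for node in tree.preorder_node_iter():
        node.age_ = node.age * scale
        if node.is_leaf():
            node.age_ = 0.0
    for leaf, label in zip(tree.leaf_node_iter(), labels):
        leaf.taxon = None
        leaf.label = label
    root = tree.seed_node
    root.parent_node = None
    return root


def _basal_ladder(core: dendropy.Node, basal: list[dendropy.Node],
                  lo: float, hi: float) -> dendropy.Node:
    """Attach basal tips successively above ``core``.

    ``basal`` is ordered deepest-branching first; the first tip joins at
    age ``hi`` so Gloeobacter ends up first-branching.
    """
    if not basal:
        return core
    tips = list(reversed(basal))  # shallowest joins first
    if core is None:
        core = tips.pop(0)
    if not tips:
        return core
    ages = np.linspace(lo, hi, num=len(tips) + 1)[1:]  # ascending, lo excluded
    node = core
    for tip, age in zip(tips, ages):
        node = _join([node, tip], age)
    return node


def _ages_to_lengths(root: dendropy.Node) -> dendropy.Tree:
    tree = dendropy.Tree(seed_node=root)
    tns = tree.taxon_namespace
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            length = node.parent_node.age_ - node.age_
            if length < -1e-12:
                raise SimulationError(
                    f"incompatible ages: {node.parent_node.age_} above {node.age_}"
                )
            node.edge.length = max(length, 0.0)
        if node.is_leaf():
            node.taxon = tns.require_taxon(node.label)
            node.label = None
    return tree


def apply_rate_noise(tree: PhyloTree, sigma: float, seed) -> PhyloTree:
    """Multiply every branch by an independent lognormal factor.

    Factors have log-mean ``-sigma**2 / 2`` and log-SD ``sigma`` so their
    expectation is 1; ``sigma = 0`` returns the tree unchanged.
    """
    if sigma < 0:
        raise SimulationError("sigma must be nonnegative")
    if sigma == 0:
        return tree.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = tree.copy()
    for node in out.nodes():
        if node.parent_node is None:
            continue
        factor = float(rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma))
        node.edge.length = node.edge.length * factor
    return out


# -- assembly ---------------------------------------------------------------

def _make_labels(prefix: str, n: int) -> list[str]:
    return [f"{prefix}_{i + 1:02d}" for i in range(n)]


def simulate_tree(config: SimConfig) -> SimBundle:
    """Generate one bundle: Newick + taxonomy TSV + ground truth."""
    config.validate()
    cfg = config
    rng = random.Random(cfg.seed)
    A = cfg.d_arch + cfg.s  # attachment age of the archaeplastida stem
    records: list[TaxonRecord] = []

    def clade(group: str, subgroup: str, prefix: str, n: int, depth: float):
        if n == 0:
            return None
        labels = _make_labels(prefix, n)
        for label in labels:
            records.append(TaxonRecord(label, group, subgroup))
        return _yule_clade(labels, depth, rng)

    # archaeplastida complex (absent for T5)
    arch = None
    if cfg.tree_type != "T5":
        green = _join(
            [clade("green", "chlorophyte", "chlorophyte", cfg.n_chlorophyte,
                   0.6 * cfg.d_green),
             clade("green", "streptophyte", "streptophyte", cfg.n_streptophyte,
                   0.6 * cfg.d_green)],
            cfg.d_green,
        )
        red = _join(
            [clade("red", "cyanidiophytina", "cyanidiophytina", cfg.n_cyanidiophytina,
                   0.6 * cfg.d_red),
             clade("red", "rhodophytina", "rhodophytina", cfg.n_rhodophytina,
                   0.6 * cfg.d_red)],
            cfg.d_red,
        )
        arch = _join([green, red], cfg.d_arch)

    basal_tips: list[dendropy.Node] = []
    for i in range(cfg.n_basal):
        subgroup = BASAL_LADDER[i % 3]
        label = f"{subgroup}_{i // 3 + 1:02d}"
        records.append(TaxonRecord(label, "cyanobacteria", subgroup))
        basal_tips.append(_leaf(label))

    def alpha_beta(alpha_crown: float, beta_crown: float, ab_age: float):
        """The alpha/beta core of the cyanobacterial clade."""
        alpha = clade("cyanobacteria", "alpha", "alpha", cfg.n_alpha, alpha_crown)
        beta = clade("cyanobacteria", "beta", "beta", cfg.n_beta, beta_crown)
        if alpha is not None and beta is not None:
            return _join([alpha, beta], ab_age)
        return alpha if alpha is not None else beta

    # outgroup clades joined above the core, 25% older per step, each with
    # its crown at 70% of its own join age
    outer: list[tuple[str, str, str, int]] = []

    if cfg.tree_type in ("T1", "T1c"):
        if cfg.sub_origin in ("alpha", "beta"):
            alpha = clade("cyanobacteria", "alpha", "alpha", cfg.n_alpha, 0.7 * A)
            beta = clade("cyanobacteria", "beta", "beta", cfg.n_beta, 0.7 * A)
            target, other = (alpha, beta) if cfg.sub_origin == "alpha" else (beta, alpha)
            attach = _join([target, arch], A)  # the stem joins the target subclade
            ab = _join([attach, other], 1.3 * A) if other is not None else attach
            core = _basal_ladder(ab, basal_tips, 1.45 * A, 1.7 * A)
        else:  # deep: below the alpha/beta split, with only basal taxa above
            ab = alpha_beta(0.5 * A, 0.5 * A, 0.8 * A)
            attach = _join([ab, arch], A)
            core = _basal_ladder(attach, basal_tips, 1.2 * A, 1.45 * A)
        root = core
        if cfg.tree_type == "T1":
            outer = [("bacteria_other", "proteobacteria", "bact", cfg.n_bact_other),
                     ("eukaryote_other", "", "euk", cfg.n_euk_other)]
    elif cfg.tree_type == "T2":
        ab = alpha_beta(0.25 * A, 0.25 * A, 0.4 * A)
        cyano = _basal_ladder(ab, basal_tips, 0.55 * A, 0.8 * A)
        root = _join([cyano, arch], A)
        outer = [("bacteria_other", "proteobacteria", "bact", cfg.n_bact_other),
                 ("eukaryote_other", "", "euk", cfg.n_euk_other)]
    elif cfg.tree_type in ("T3", "T4"):
        if cfg.tree_type == "T3":
            sister = clade("bacteria_other", "proteobacteria", "bact",
                           cfg.n_bact_other, 0.7 * A)
            outer = [("eukaryote_other", "", "euk", cfg.n_euk_other)]
        else:
            sister = clade("eukaryote_other", "", "euk", cfg.n_euk_other, 0.7 * A)
            outer = [("bacteria_other", "proteobacteria", "bact", cfg.n_bact_other)]
        root = _join([sister, arch], A)
        # an ordinary cyanobacterial clade elsewhere in the tree
        ab = alpha_beta(0.3 * A, 0.3 * A, 0.5 * A)
        cyano = _basal_ladder(ab, basal_tips, 0.6 * A, 0.75 * A) if ab is not None else None
        if cyano is not None:
            root = _join([root, cyano], 1.25 * max(root.age_, cyano.age_))
    else:  # T5: cyanobacteria with bacterial/eukaryotic outgroups only
        ab = alpha_beta(0.5, 0.5, 0.8)
        root = _basal_ladder(ab, basal_tips, 1.0, 1.3)
        outer = [("bacteria_other", "proteobacteria", "bact", cfg.n_bact_other),
                 ("eukaryote_other", "", "euk", cfg.n_euk_other)]

    for group, subgroup, prefix, n in outer:
        if n == 0:
            continue
        join_age = 1.25 * root.age_
        og = clade(group, subgroup, prefix, n, 0.7 * join_age)
        root = _join([root, og], join_age)

    time_tree = PhyloTree(_ages_to_lengths(root), rooted=True)
    taxa = TaxonMap(records)
    atree = annotate(time_tree, taxa)
    truth = _measure_truth(cfg, atree)
    noisy = apply_rate_noise(time_tree, cfg.sigma, np.random.default_rng(cfg.seed))
    return SimBundle(noisy.to_newick(), taxa.to_tsv(), truth, cfg)


def _measure_truth(cfg: SimConfig, atree: AnnotatedTree) -> dict:
    """Record the generating truth by measuring the noiseless time tree."""
    if cfg.tree_type in ("T1", "T1c"):
        sub = cfg.sub_origin
    elif cfg.tree_type == "T2":
        # the sister is the whole cyanobacterial clade; its composition
        # decides the sub-origin the classifier should report
        subgroups = {
            atree.records[l].subgroup for l in atree.tips_in_group("cyanobacteria")
        }
        if subgroups & set(BASAL_LADDER) or {"alpha", "beta"} <= subgroups:
            sub = "deep"
        else:
            sub = "alpha" if "alpha" in subgroups else "beta"
    else:
        sub = "none"
    if cfg.tree_type == "T1c":
        rooting = "basal:gloeobacter"
    elif cfg.tree_type == "T4":
        rooting = "outgroup:bacteria_other"
    elif cfg.n_euk_other > 0:
        rooting = "outgroup:eukaryote_other"
    else:
        rooting = "outgroup:bacteria_other"
    lineages: dict[str, dict] = {}
    if cfg.tree_type != "T5":
        for lineage in ("green", "red"):
            lineages[lineage] = {}
            for mode in ("clade_branches", "tip_depth"):
                m = stems_mod.stem_metrics(atree, lineage, mode=mode)
                lineages[lineage][mode] = {
                    "S": m.S, "L": m.L, "ratio": m.ratio,
                    "CL": m.CL, "cl_ratio": m.cl_ratio,
                }
    return {
        "tree_type": cfg.tree_type,
        "sub_origin": sub,
        "rooting": rooting,
        "lineages": lineages,
        "params": asdict(cfg),
    }
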