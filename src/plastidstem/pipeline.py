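"""Batch driver: many proteins x inference methods in, one summary out.

A batch configuration (YAML or dict) lists per-protein tree files, the
shared taxonomy table, a rooting directive per protein, and which proteins
constitute the canonical reference set.  For every protein x method x
lineage the driver roots the tree, classifies the origin type, and
measures stem metrics; per-method values are combined as geometric means,
the reference point is estimated from the reference set, and each protein
receives earlier/canonical/later timing categories.  A failing protein is
recorded and skipped — one corrupt Newick must not kill a hundred-protein
run — and the run exits nonzero if anything failed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .tree_core import read_newick
from .taxonomy import load_taxon_map, annotate, AnnotatedTree, TaxonRecord
from .rooting import root_tree
from .classify import classify_lineage, DEFAULT_K_INTRUDERS, DEFAULT_PURITY
from .stems import (
    stem_metrics,
    combine_methods,
    reference_point,
    compare_to_reference,
    StemError,
)

__all__ = ["BatchConfig", "BatchResult", "ProteinEntry", "load_batch_config", "run_batch"]

SUMMARY_COLUMNS = [
    "protein", "method", "lineage", "tree_type", "sub_origin", "separated",
    "status", "sister_profile", "S", "L", "ratio", "CL", "cl_ratio",
    "timing_stem", "timing_cl", "error",
]


@dataclass
class ProteinEntry:
    name: str
    trees: dict[str, str]  # method -> newick path
    lineages: list[str] = field(default_factory=lambda: ["green", "red"])
    root: str = "mad"
    rogue: list[str] = field(default_factory=list)


@dataclass
class BatchConfig:
    proteins: list[ProteinEntry]
    taxonomy: str
    taxonomy_regex: bool = False
    mode: str = "clade_branches"
    k_intruders: int = DEFAULT_K_INTRUDERS
    purity: float = DEFAULT_PURITY
    reference_proteins: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    base_dir: Path = Path(".")

    def validate(self) -> None:
        if not self.proteins:
            raise ValueError("batch config lists no proteins")
        names = [p.name for p in self.proteins]
        if len(names) != len(set(names)):
            raise ValueError("protein names must be unique")

    def resolve(self, path: str) -> Path:
        p = Path(path)
        return p if p.is_absolute() else self.base_dir / p


@dataclass
class BatchResult:
    summary: pd.DataFrame
    scatter: pd.DataFrame
    reference: object  # ReferencePoint or None
    log: dict
    errors: list[str]

    @property
    def ok(self) -> bool:
        return not self.errors


def load_batch_config(path) -> BatchConfig:
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    proteins = [
        ProteinEntry(
            name=entry["name"],
            trees=dict(entry["trees"]),
            lineages=list(entry.get("lineages", ["green", "red"])),
            root=entry.get("root", "mad"),
            rogue=list(entry.get("rogue", [])),
        )
        for entry in raw.get("proteins", [])
    ]
    return BatchConfig(
        proteins=proteins,
        taxonomy=raw["taxonomy"],
        taxonomy_regex=bool(raw.get("taxonomy_regex", False)),
        mode=raw.get("mode", "clade_branches"),
        k_intruders=int(raw.get("k_intruders", DEFAULT_K_INTRUDERS)),
        purity=float(raw.get("purity", DEFAULT_PURITY)),
        reference_proteins=list(raw.get("reference_proteins", [])),
        outputs=dict(raw.get("outputs", {})),
        seed=int(raw.get("seed", 0)),
        base_dir=path.parent,
    )


def _with_rogues(atree: AnnotatedTree, rogue: list[str]) -> AnnotatedTree:
    if not rogue:
        return atree
    records = dict(atree.records)
    for label in rogue:
        if label in records:
            rec = records[label]
            records[label] = TaxonRecord(
                rec.tip_label, rec.group, rec.subgroup, rec.flags | {"rogue"}
            )
    return AnnotatedTree(atree.tree, records, atree.counts, atree.warnings)


def _analyze_protein(config: BatchConfig, entry: ProteinEntry, taxa,
                     rows: list[dict], decisions: list[str]):
    """Per-method classification and metrics; returns combined per lineage."""
    per_lineage: dict[str, list] = {l: [] for l in entry.lineages}
    calls: dict[tuple[str, str], object] = {}
    for method, tree_path in sorted(entry.trees.items()):
        tree = read_newick(config.resolve(tree_path))
        atree = annotate(tree, taxa, allow_unknown=True)
        if atree.warnings:
            decisions.extend(f"{entry.name}/{method}: {w}" for w in atree.warnings)
        atree = _with_rogues(atree, entry.rogue)
        rooted = root_tree(atree.tree, taxa, entry.root)
        for warning in rooted.warnings:
            decisions.append(f"{entry.name}/{method}: {warning}")
        ratree = annotate(rooted, taxa, allow_unknown=True)
        ratree = _with_rogues(ratree, entry.rogue)
        for lineage in entry.lineages:
            call = classify_lineage(
                ratree, lineage, config.k_intruders, config.purity, method
            )
            calls[(method, lineage)] = call
            row = {
                "protein": entry.name, "method": method, "lineage": lineage,
                "tree_type": call.tree_type, "sub_origin": call.sub_origin,
                "separated": call.separated_lineages, "status": call.status,
                "sister_profile": call.profile_json(),
            }
            if call.status == "tolerated":
                decisions.append(
                    f"{entry.name}/{method}/{lineage}: tolerated intruders in crown clade"
                )
            try:
                m = stem_metrics(ratree, lineage, config.mode, method,
                                 config.k_intruders)
                row.update(S=m.S, L=m.L, ratio=m.ratio, CL=m.CL, cl_ratio=m.cl_ratio)
                if m.CL is None:
                    decisions.append(
                        f"{entry.name}/{method}/{lineage}: no cyanobacterial neighbor, "
                        "CL missing"
                    )
                per_lineage[lineage].append(m)
            except StemError as exc:
                decisions.append(f"{entry.name}/{method}/{lineage}: {exc}")
            rows.append(row)
    # method-consistency flag: differing per-method type calls are reported,
    # never adjudicated
    for lineage in entry.lineages:
        types = {c.tree_type for (m, l), c in calls.items() if l == lineage}
        if len(types) > 1:
            decisions.append(
                f"{entry.name}/{lineage}: methods disagree on tree type "
                f"({', '.join(sorted(types))})"
            )
    combined = {}
    for lineage, metrics in per_lineage.items():
        if metrics:
            combined[lineage] = combine_methods(metrics)
    return combined, calls


def run_batch(config: BatchConfig) -> BatchResult:
    config.validate()
    taxa = load_taxon_map(config.resolve(config.taxonomy), regex=config.taxonomy_regex)
    rows: list[dict] = []
    decisions: list[str] = []
    errors: list[str] = []
    combined_all: dict[str, dict] = {}
    call_types: dict[str, dict[str, tuple[str, str]]] = {}
    for entry in config.proteins:
        try:
            combined, calls = _analyze_protein(config, entry, taxa, rows, decisions)
            combined_all[entry.name] = combined
            call_types[entry.name] = {}
            for (method, lineage), call in sorted(calls.items()):
                call_types[entry.name][lineage] = (call.tree_type, call.sub_origin)
        except Exception as exc:  # per-protein isolation
            errors.append(f"{entry.name}: {exc}")
            rows.append({"protein": entry.name, "method": "", "lineage": "",
                         "error": str(exc)})

    # reference point from the configured canonical set
    ref = None
    ref_rows = []
    for name in config.reference_proteins:
        combined = combined_all.get(name, {})
        green = combined.get("green")
        red = combined.get("red")
        ref_rows.append((
            name,
            green.ratio if green else None,
            red.ratio if red else None,
            green.cl_ratio if green else None,
        ))
    if ref_rows and any(r[1] or r[2] or r[3] for r in ref_rows):
        ref = reference_point(ref_rows)

    # combined rows with timing categories
    scatter_rows: list[dict] = []
    for name, combined in combined_all.items():
        scatter = {"protein": name}
        for lineage, cm in combined.items():
            timing = compare_to_reference(cm, ref) if ref else {}
            stem_axis = "vs_vl" if lineage == "green" else "rs_rl"
            rows.append({
                "protein": name, "method": "combined", "lineage": lineage,
                "tree_type": call_types[name].get(lineage, ("", ""))[0],
                "sub_origin": call_types[name].get(lineage, ("", ""))[1],
                "ratio": cm.ratio, "cl_ratio": cm.cl_ratio,
                "timing_stem": timing.get(stem_axis, ""),
                "timing_cl": timing.get("cl_vl", ""),
            })
            scatter[stem_axis] = cm.ratio
            if lineage == "green":
                scatter["cl_vl"] = cm.cl_ratio
        scatter_rows.append(scatter)

    summary = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    scatter = pd.DataFrame(scatter_rows, columns=["protein", "vs_vl", "rs_rl", "cl_vl"])
    log = {
        "version": __version__,
        "seed": config.seed,
        "n_proteins": len(config.proteins),
        "decisions": decisions,
        "errors": errors,
        "reference_point": (
            {"vs_vl": ref.vs_vl, "rs_rl": ref.rs_rl, "cl_vl": ref.cl_vl,
             "bands": {k: list(v) for k, v in ref.bands.items()}}
            if ref else None
        ),
    }
    result = BatchResult(summary, scatter, ref, log, errors)
    _write_outputs(config, result)
    return result


def _write_outputs(config: BatchConfig, result: BatchResult) -> None:
    out = config.outputs
    if "summary" in out:
        result.summary.to_csv(config.resolve(out["summary"]), sep="\t",
                              index=False, float_format="%.10g")
    if "scatter" in out:
        result.scatter.to_csv(config.resolve(out["scatter"]), sep="\t",
                              index=False, float_format="%.10g")
    if "log" in out:
        config.resolve(out["log"]).write_text(
            json.dumps(result.log, indent=1, sort_keys=True) + "\n"
        )
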