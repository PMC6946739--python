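"""Tip-label taxonomy: lineage groups, subgroups, and analysis flags.

Tips are assigned to one of six groups.  ``green`` (Viridiplantae),
``red`` (Rhodophyta) and ``glaucophyte`` together form the Archaeplastida;
``cyanobacteria`` are the candidate gene donors; ``bacteria_other`` and
``eukaryote_other`` hold every remaining homolog.  Subgroups refine the
placement within a group: chlorophyte/streptophyte under green,
cyanidiophytina/rhodophytina under red, and alpha/beta plus the basal taxa
(gloeobacter, Yellowstone *Synechococcus*, *Pseudanabaena*) within
cyanobacteria.

Flags carry per-tip analysis directives: ``cl_exclude`` removes long-branch
marine picocyanobacteria from the cyanobacterial rate reference,
``rogue`` prunes a tip before any clade or stem measurement, and
``chloroplast_encoded`` is bookkeeping only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .tree_core import PhyloTree

__all__ = [
    "TaxonRecord",
    "TaxonMap",
    "AnnotatedTree",
    "TaxonomyError",
    "load_taxon_map",
    "annotate",
    "GROUPS",
    "ARCHAEPLASTIDA",
    "BASAL_CYANO_SUBGROUPS",
]

GROUPS = frozenset(
    {"green", "red", "glaucophyte", "cyanobacteria", "bacteria_other", "eukaryote_other"}
)
ARCHAEPLASTIDA = frozenset({"green", "red", "glaucophyte"})
GREEN_SUBGROUPS = frozenset({"chlorophyte", "streptophyte"})
RED_SUBGROUPS = frozenset({"cyanidiophytina", "rhodophytina"})
BASAL_CYANO_SUBGROUPS = frozenset({"gloeobacter", "yellowstone", "pseudanabaena"})
CYANO_SUBGROUPS = frozenset({"alpha", "beta"}) | BASAL_CYANO_SUBGROUPS
FLAGS = frozenset({"cl_exclude", "rogue", "chloroplast_encoded"})

#: group used when a tip is absent from the map and unknowns are allowed
UNKNOWN_GROUP = "unknown"


class TaxonomyError(ValueError):
    pass


@dataclass(frozen=True)
class TaxonRecord:
    tip_label: str
    group: str
    subgroup: str = ""
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.group not in GROUPS and self.group != UNKNOWN_GROUP:
            raise TaxonomyError(
                f"unknown group {self.group!r} for tip {self.tip_label!r}"
            )
        bad = set(self.flags) - FLAGS
        if bad:
            raise TaxonomyError(f"unknown flags {sorted(bad)} for tip {self.tip_label!r}")
        if self.subgroup in GREEN_SUBGROUPS and self.group != "green":
            raise TaxonomyError(
                f"subgroup {self.subgroup!r} only valid under green ({self.tip_label!r})"
            )
        if self.subgroup in RED_SUBGROUPS and self.group != "red":
            raise TaxonomyError(
                f"subgroup {self.subgroup!r} only valid under red ({self.tip_label!r})"
            )
        if "cl_exclude" in self.flags and self.group != "cyanobacteria":
            raise TaxonomyError(
                f"cl_exclude flag only meaningful for cyanobacteria ({self.tip_label!r})"
            )


class TaxonMap:
    """Ordered tip-label -> :class:`TaxonRecord` lookup.

    With ``regex=True``, each record's ``tip_label`` is treated as a
    pattern anchored at the start of the queried label, so e.g. one row
    ``alpha_`` can cover every *Prochlorococcus* strain emitted by the
    simulator.  Exact matches take precedence over pattern matches.
    """

    def __init__(self, records, regex: bool = False):
        self.regex = regex
        self._records: dict[str, TaxonRecord] = {}
        for rec in records:
            if rec.tip_label in self._records:
                raise TaxonomyError(f"duplicate tip_label {rec.tip_label!r}")
            self._records[rec.tip_label] = rec

    def __len__(self):
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def lookup(self, label: str) -> TaxonRecord | None:
        rec = self._records.get(label)
        if rec is not None or not self.regex:
            return rec
        for key, rec in self._records.items():
            if re.match(key, label):
                return TaxonRecord(label, rec.group, rec.subgroup, rec.flags)
        return None

    def to_tsv(self) -> str:
        lines = ["tip_label\tgroup\tsubgroup\tflags"]
        for rec in self._records.values():
            lines.append(
                "\t".join(
                    [rec.tip_label, rec.group, rec.subgroup, ",".join(sorted(rec.flags))]
                )
            )
        return "\n".join(lines) + "\n"


def load_taxon_map(path, regex: bool = False) -> TaxonMap:
    """Read a taxonomy TSV (columns tip_label, group, subgroup, flags)."""
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"tip_label", "group", "subgroup", "flags"}
    missing = required - set(table.columns)
    if missing:
        raise TaxonomyError(f"taxonomy table missing columns {sorted(missing)}")
    records = []
    for idx, row in table.iterrows():
        try:
            flags = frozenset(f for f in row["flags"].split(",") if f)
            records.append(
                TaxonRecord(row["tip_label"], row["group"], row["subgroup"], flags)
            )
        except TaxonomyError as exc:
            raise TaxonomyError(f"row {idx + 2}: {exc}") from exc
    return TaxonMap(records, regex=regex)


@dataclass
class AnnotatedTree:
    """A tree whose every tip carries a taxon record."""

    tree: PhyloTree
    records: dict[str, TaxonRecord]
    counts: dict[str, int]
    warnings: list[str] = field(default_factory=list)

    def record(self, label: str) -> TaxonRecord:
        return self.records[label]

    def group_of(self, label: str) -> str:
        return self.records[label].group

    def tips_in_group(self, group: str) -> set[str]:
        return {l for l, r in self.records.items() if r.group == group}

    def tips_in_subgroup(self, subgroup: str) -> set[str]:
        return {l for l, r in self.records.items() if r.subgroup == subgroup}

    def tips_with_flag(self, flag: str) -> set[str]:
        return {l for l, r in self.records.items() if flag in r.flags}

    def without_rogues(self) -> "AnnotatedTree":
        """Prune rogue-flagged tips; unifurcations are collapsed so branch
        lengths along a former chain are summed."""
        rogue = self.tips_with_flag("rogue")
        if not rogue:
            return self
        keep = [l for l in self.tree.tip_labels() if l not in rogue]
        if len(keep) < 2:
            raise TaxonomyError("pruning rogue tips leaves fewer than 2 tips")
        pruned = self.tree.copy()
        pruned._dt.retain_taxa_with_labels(keep)
        pruned._dt.suppress_unifurcations()
        new_records = {l: r for l, r in self.records.items() if l not in rogue}
        counts: dict[str, int] = {}
        for rec in new_records.values():
            counts[rec.group] = counts.get(rec.group, 0) + 1
        return AnnotatedTree(
            PhyloTree(pruned._dt, rooted=self.tree.rooted),
            new_records,
            counts,
            self.warnings + [f"pruned rogue tips: {sorted(rogue)}"],
        )


def annotate(tree: PhyloTree, taxa: TaxonMap, allow_unknown: bool = False) -> AnnotatedTree:
    """Attach taxon records to every tip of ``tree``.

    Unmapped tips are an error unless ``allow_unknown`` is set, in which
    case they receive the ``unknown`` pseudo-group (classification treats
    them as intruders) and a warning is recorded.
    """
    records: dict[str, TaxonRecord] = {}
    warnings: list[str] = []
    unmapped: list[str] = []
    for label in tree.tip_labels():
        rec = taxa.lookup(label)
        if rec is None:
            unmapped.append(label)
            records[label] = TaxonRecord(label, UNKNOWN_GROUP)
        else:
            records[label] = rec
    if unmapped:
        if not allow_unknown:
            raise TaxonomyError(f"tips absent from taxonomy: {sorted(unmapped)}")
        warnings.append(f"tips absent from taxonomy, tagged unknown: {sorted(unmapped)}")
    counts: dict[str, int] = {}
    for rec in records.values():
        counts[rec.group] = counts.get(rec.group, 0) + 1
    return AnnotatedTree(tree, records, counts, warnings)
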