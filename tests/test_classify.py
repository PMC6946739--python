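import pytest

from plastidstem import parse_newick
from plastidstem.taxonomy import TaxonRecord, TaxonMap, annotate
from plastidstem.classify import (
    ClassifyError,
    lineage_clade,
    classify_lineage,
    suborigin,
)

from conftest import FIX1, fix1_records


def _atree(newick, records):
    return annotate(parse_newick(newick), TaxonMap(records))


def test_lineage_clade_clean(fix1_atree):
    clade = lineage_clade(fix1_atree, "green", 0)
    assert clade.tips == {"G1", "G2"}
    assert clade.intruders == set()
    assert clade.status == "clean"


def test_lineage_clade_intruder_tolerance():
    records = fix1_records() + [TaxonRecord("B2", "bacteria_other")]
    newick = FIX1.replace("G1:1.0,G2:1.0", "G1:1.0,(G2:0.5,B2:0.5):0.5")
    atree = _atree(newick, records)
    assert lineage_clade(atree, "green", 0).status == "unresolved"
    clade = lineage_clade(atree, "green", 1)
    assert clade.status == "tolerated"
    assert clade.intruders == {"B2"}


def test_lineage_absent_raises(fix1_atree):
    records = [r for r in fix1_records() if r.group != "red"] + [
        TaxonRecord("R1", "bacteria_other"), TaxonRecord("R2", "bacteria_other"),
    ]
    atree = _atree(FIX1, records)
    with pytest.raises(ClassifyError, match="lineage absent"):
        lineage_clade(atree, "red", 0)


def test_sister_to_whole_cyano_clade_is_type2(fix1_atree):
    for lineage in ("green", "red"):
        call = classify_lineage(fix1_atree, lineage)
        assert call.tree_type == "T2"
        assert call.sister_profile == {"cyanobacteria": 1.0}
        assert call.separated_lineages is False
        # whole-clade sister includes alpha and beta: deep origin
        assert call.sub_origin == "deep"


def test_nested_in_cyanobacteria_is_type1_alpha(fix2_atree):
    call = classify_lineage(fix2_atree, "green")
    assert call.tree_type == "T1"
    assert call.sub_origin == "alpha"
    assert call.sister_tips == {"Ca1", "Ca2"}


def test_eukaryote_sister_is_type4():
    records = [
        TaxonRecord("G1", "green", "chlorophyte"),
        TaxonRecord("G2", "green", "streptophyte"),
        TaxonRecord("E1", "eukaryote_other"), TaxonRecord("E2", "eukaryote_other"),
        TaxonRecord("B1", "bacteria_other"),
    ]
    atree = _atree("(((G1:1,G2:1):0.5,(E1:1.2,E2:1.2):0.4):0.3,B1:2);", records)
    call = classify_lineage(atree, "green")
    assert call.tree_type == "T4"
    assert call.sub_origin == "none"


def test_bacteria_sister_is_type3():
    records = [
        TaxonRecord("G1", "green", "chlorophyte"),
        TaxonRecord("G2", "green", "streptophyte"),
        TaxonRecord("P1", "bacteria_other"), TaxonRecord("P2", "bacteria_other"),
        TaxonRecord("E1", "eukaryote_other"),
    ]
    atree = _atree("(((G1:1,G2:1):0.5,(P1:1.2,P2:1.2):0.4):0.3,E1:2);", records)
    assert classify_lineage(atree, "green").tree_type == "T3"


def test_no_chloroplast_lineages_is_type5():
    records = [
        TaxonRecord("C1", "cyanobacteria", "alpha"),
        TaxonRecord("C2", "cyanobacteria", "beta"),
        TaxonRecord("B1", "bacteria_other"),
    ]
    atree = _atree("((C1:1,C2:1):0.5,B1:2);", records)
    for lineage in ("green", "red"):
        assert classify_lineage(atree, lineage).tree_type == "T5"


def test_no_outgroup_downgrades_to_type1c():
    # FIX2 without the bacterial tip: only cyanobacteria + Archaeplastida
    records = [
        TaxonRecord("G1", "green", "chlorophyte"),
        TaxonRecord("G2", "green", "streptophyte"),
        TaxonRecord("R1", "red", "cyanidiophytina"),
        TaxonRecord("R2", "red", "rhodophytina"),
        TaxonRecord("Ca1", "cyanobacteria", "alpha"),
        TaxonRecord("Ca2", "cyanobacteria", "alpha"),
        TaxonRecord("Cb1", "cyanobacteria", "beta"),
    ]
    newick = (
        "((((G1:1.0,G2:1.0):0.4,(R1:1.0,R2:1.0):0.4):0.6,"
        "(Ca1:0.8,Ca2:0.8):0.7):0.3,Cb1:1.9);"
    )
    call = classify_lineage(_atree(newick, records), "green")
    assert call.tree_type == "T1c"
    assert call.sub_origin == "alpha"


def test_low_purity_sister_is_unresolved():
    records = [
        TaxonRecord("G1", "green", "chlorophyte"),
        TaxonRecord("G2", "green", "streptophyte"),
        TaxonRecord("P1", "bacteria_other"), TaxonRecord("E1", "eukaryote_other"),
        TaxonRecord("B1", "bacteria_other"),
    ]
    atree = _atree("(((G1:1,G2:1):0.5,(P1:1.2,E1:1.2):0.4):0.3,B1:2);", records)
    call = classify_lineage(atree, "green", purity=0.8)
    assert call.tree_type == "unresolved"


def test_separated_lineages_flagged():
    # green and red attach at different points within cyanobacteria ([RG])
    records = [
        TaxonRecord("G1", "green", "chlorophyte"),
        TaxonRecord("G2", "green", "streptophyte"),
        TaxonRecord("R1", "red", "cyanidiophytina"),
        TaxonRecord("R2", "red", "rhodophytina"),
        TaxonRecord("Ca1", "cyanobacteria", "alpha"),
        TaxonRecord("Ca2", "cyanobacteria", "alpha"),
        TaxonRecord("Cb1", "cyanobacteria", "beta"),
        TaxonRecord("Cb2", "cyanobacteria", "beta"),
        TaxonRecord("B1", "bacteria_other"),
    ]
    newick = (
        "((((G1:1,G2:1):0.5,(Ca1:1,Ca2:1):0.5):0.5,"
        "((R1:1,R2:1):0.5,(Cb1:1,Cb2:1):0.5):0.5):0.5,B1:2);"
    )
    atree = _atree(newick, records)
    green = classify_lineage(atree, "green")
    red = classify_lineage(atree, "red")
    assert green.separated_lineages and red.separated_lineages
    assert (green.tree_type, green.sub_origin) == ("T1", "alpha")
    assert (red.tree_type, red.sub_origin) == ("T1", "beta")


def test_suborigin_rules(fix1_atree, fix2_atree):
    call = classify_lineage(fix2_atree, "green")
    assert suborigin(fix2_atree, call) == "alpha"
    # mixed alpha + beta sister (whole cyano clade in FIX1) is deep
    call1 = classify_lineage(fix1_atree, "green")
    assert suborigin(fix1_atree, call1) == "deep"
    # gloeobacter in the sister set forces deep
    records = [
        TaxonRecord("G1", "green", "chlorophyte"),
        TaxonRecord("G2", "green", "streptophyte"),
        TaxonRecord("R1", "red", "cyanidiophytina"),
        TaxonRecord("R2", "red", "rhodophytina"),
        TaxonRecord("C1", "cyanobacteria", "gloeobacter"),
        TaxonRecord("C2", "cyanobacteria", "alpha"),
        TaxonRecord("B1", "bacteria_other"),
    ]
    from conftest import FIX1 as newick
    atree = _atree(newick, records)
    assert classify_lineage(atree, "green").sub_origin == "deep"
    # sub-origin is undefined for non-cyanobacterial origins
    t4_call = classify_lineage(fix1_atree, "green")
    t4_call.tree_type = "T4"
    with pytest.raises(ClassifyError, match="undefined"):
        suborigin(fix1_atree, t4_call)


def test_classification_invariances(fix2_atree):
    base = classify_lineage(fix2_atree, "green")
    taxa = TaxonMap(list(fix2_atree.records.values()))
    scaled = annotate(fix2_atree.tree.scale(3.7), taxa)
    call = classify_lineage(scaled, "green")
    assert (call.tree_type, call.sub_origin) == (base.tree_type, base.sub_origin)
    # rerooting with the same outgroup convention leaves the call unchanged
    from plastidstem.rooting import root_by_outgroup

    rerooted = annotate(
        root_by_outgroup(fix2_atree.tree, taxa, "bacteria_other"), taxa
    )
    call2 = classify_lineage(rerooted, "green")
    assert (call2.tree_type, call2.sub_origin) == (base.tree_type, base.sub_origin)
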