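import pytest

from plastidstem import parse_newick
from plastidstem.taxonomy import TaxonRecord, TaxonMap, annotate

# seven-tip reference tree: green + red sister clades, cyanobacterial
# sister group, one bacterial outgroup
FIX1 = (
    "((((G1:1.0,G2:1.0):0.5,(R1:1.0,R2:1.0):0.5):1.0,"
    "(C1:0.6,C2:0.6):0.9):0.2,B1:2.0);"
)

# archaeplastida nested inside cyanobacteria (alpha sister, beta outside)
FIX2 = (
    "(((((G1:1.0,G2:1.0):0.4,(R1:1.0,R2:1.0):0.4):0.6,"
    "(Ca1:0.8,Ca2:0.8):0.7):0.3,Cb1:1.9):0.2,B1:2.5);"
)


def fix1_records():
    return [
        TaxonRecord("G1", "green", "chlorophyte"),
        TaxonRecord("G2", "green", "streptophyte"),
        TaxonRecord("R1", "red", "cyanidiophytina"),
        TaxonRecord("R2", "red", "rhodophytina"),
        TaxonRecord("C1", "cyanobacteria", "alpha"),
        TaxonRecord("C2", "cyanobacteria", "beta"),
        TaxonRecord("B1", "bacteria_other", "proteobacteria"),
    ]


@pytest.fixture
def fix1_tree():
    return parse_newick(FIX1)


@pytest.fixture
def fix1_taxa():
    return TaxonMap(fix1_records())


@pytest.fixture
def fix1_atree(fix1_tree, fix1_taxa):
    return annotate(fix1_tree, fix1_taxa)


@pytest.fixture
def fix2_atree():
    records = [
        TaxonRecord("G1", "green", "chlorophyte"),
        TaxonRecord("G2", "green", "streptophyte"),
        TaxonRecord("R1", "red", "cyanidiophytina"),
        TaxonRecord("R2", "red", "rhodophytina"),
        TaxonRecord("Ca1", "cyanobacteria", "alpha"),
        TaxonRecord("Ca2", "cyanobacteria", "alpha"),
        TaxonRecord("Cb1", "cyanobacteria", "beta"),
        TaxonRecord("B1", "bacteria_other", "proteobacteria"),
    ]
    return annotate(parse_newick(FIX2), TaxonMap(records))
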