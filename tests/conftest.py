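"""Shared fixtures: genetic codes, hand-built count tables, a GenBank
fixture written programmatically at test time."""

import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from codonbias.codon_core import CodonCountTable, load_genetic_code


@pytest.fixture(scope="session")
def code():
    return load_genetic_code(1)


@pytest.fixture(scope="session")
def code4():
    return load_genetic_code(4)


def table_from_counts(counts, code, source="toy"):
    """Build a CodonCountTable directly from a codon->count mapping."""
    return CodonCountTable(
        counts=dict(counts),
        total_codons=sum(counts.values()),
        source=source,
        code=code,
    )


@pytest.fixture
def make_table(code):
    def _make(counts, source="toy", use_code=None):
        return table_from_counts(counts, use_code or code, source)
    return _make


# ---------------------------------------------------------------------------
# GenBank fixture: one forward CDS, one spliced minus-strand CDS
# ---------------------------------------------------------------------------

#: exons of the spliced CDS, 0-based half-open on the plus strand
SPLICED_EXONS = [(500, 560), (600, 663)]
FORWARD_CDS = (10, 373)   # 363 bp


def _fixture_genome():
    import random

    rnd = random.Random(42)
    seq = "".join(rnd.choice("ACGT") for _ in range(800))
    # forward CDS: ATG ... TAA, 363 bp
    s, e = FORWARD_CDS
    body = "".join(rnd.choice("ACGT") for _ in range(e - s - 6))
    seq = seq[:s] + "ATG" + body + "TAA" + seq[e:]
    return seq


@pytest.fixture(scope="session")
def genbank_fixture(tmp_path_factory):
    """Write a small annotated GenBank file; returns (path, genome_str)."""
    genome = _fixture_genome()
    record = SeqRecord(Seq(genome), id="FIX00001", name="FIX00001",
                       description="synthetic mitochondrial fragment",
                       annotations={"molecule_type": "DNA"})
    s, e = FORWARD_CDS
    record.features.append(SeqFeature(
        SimpleLocation(s, e, strand=1), type="CDS",
        qualifiers={"gene": ["atp6"]},
    ))
    loc = CompoundLocation([SimpleLocation(a, b, strand=-1)
                            for a, b in reversed(SPLICED_EXONS)])
    record.features.append(SeqFeature(loc, type="CDS",
                                      qualifiers={"gene": ["nad3"]}))
    path = tmp_path_factory.mktemp("gb") / "fixture.gb"
    SeqIO.write(record, str(path), "genbank")
    return path, genome
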