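import json
from pathlib import Path

import pytest

from chound.genome_io import read_genome
from chound.simulate import FixtureSpec, write_fixture

# Hand-built toy annotation: one 60 bp scaffold.
#  - genA: plus strand, single CDS at 1-based 4..12 -> "MKG" + TAA stop
#  - genB: minus strand, single CDS; coding sequence (read off the minus
#    strand) is ATG AAA CTG GTG CGT AGC ACC GGC GCC TAA -> protein
#    MKLVRSTGA (9 codons), hand-translated
TOY_SCAFFOLD = (
    "AAA"              # 0-2 spacer
    "ATGAAAGGATAA"     # 3-14: genA CDS (1-based 4..15); gene feature 4..12 below
    "TTT"              # spacer
    "TTAGGCGCCGGTGCTACGCACCAGTTTCAT"  # 18-47: revcomp of genB coding seq
    "AAAAAAAAAAAA"     # pad to 60
)


@pytest.fixture(scope="session")
def toy_genome_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("toy")
    assert len(TOY_SCAFFOLD) == 60
    (d / "toy.fa").write_text(">chr1\n" + TOY_SCAFFOLD + "\n")
    gff = "\n".join(
        [
            "##gff-version 3",
            "chr1\ttest\tgene\t4\t15\t.\t+\t.\tID=genA",
            "chr1\ttest\tmRNA\t4\t15\t.\t+\t.\tID=genA.t1;Parent=genA",
            "chr1\ttest\tCDS\t4\t15\t.\t+\t0\tID=genA.c1;Parent=genA.t1",
            "chr1\ttest\tgene\t19\t48\t.\t-\t.\tID=genB",
            "chr1\ttest\tmRNA\t19\t48\t.\t-\t.\tID=genB.t1;Parent=genB",
            "chr1\ttest\tCDS\t19\t48\t.\t-\t0\tID=genB.c1;Parent=genB.t1",
        ]
    )
    (d / "toy.gff3").write_text(gff + "\n")
    return d


@pytest.fixture(scope="session")
def default_fixture_dir(tmp_path_factory):
    """One default planted-cluster fixture, generated once per session."""
    d = tmp_path_factory.mktemp("fixture")
    write_fixture(FixtureSpec(seed=11), d)
    return d


@pytest.fixture(scope="session")
def default_fixture_genome(default_fixture_dir):
    return read_genome(
        default_fixture_dir / "genome.fa", default_fixture_dir / "genome.gff3"
    )


@pytest.fixture(scope="session")
def default_fixture_truth(default_fixture_dir):
    return json.loads((default_fixture_dir / "truth.json").read_text())
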