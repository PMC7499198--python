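import io

import pytest

from svburden import (CohortManifest, GenomeIndex, load_annotation)

# Toy annotation used across tests (1-based inclusive in the file):
#   gene A chr1 1001-2000, exons 1001-1200 and 1801-2000 (intron 1201-1800)
#   gene C chr1 1051-1950, exons 1051-1080 and 1901-1950 (overlaps A)
#   gene B chr1 3000-3999, single exon
#   gene D chr2 501-1500, exons 501-700 and 1301-1500
TOY_GTF = """\
chr1\ttoy\tgene\t1001\t2000\t.\t+\t.\tgene_id "A"; gene_name "A";
chr1\ttoy\texon\t1001\t1200\t.\t+\t.\tgene_id "A"; transcript_id "A.1";
chr1\ttoy\texon\t1801\t2000\t.\t+\t.\tgene_id "A"; transcript_id "A.1";
chr1\ttoy\tgene\t1051\t1950\t.\t-\t.\tgene_id "C"; gene_name "C";
chr1\ttoy\texon\t1051\t1080\t.\t-\t.\tgene_id "C"; transcript_id "C.1";
chr1\ttoy\texon\t1901\t1950\t.\t-\t.\tgene_id "C"; transcript_id "C.1";
chr1\ttoy\tgene\t3000\t3999\t.\t+\t.\tgene_id "B"; gene_name "B";
chr1\ttoy\texon\t3000\t3999\t.\t+\t.\tgene_id "B"; transcript_id "B.1";
chr2\ttoy\tgene\t501\t1500\t.\t+\t.\tgene_id "D"; gene_name "D";
chr2\ttoy\texon\t501\t700\t.\t+\t.\tgene_id "D"; transcript_id "D.1";
chr2\ttoy\texon\t1301\t1500\t.\t+\t.\tgene_id "D"; transcript_id "D.1";
"""


@pytest.fixture(scope="session")
def toy_genes():
    return load_annotation(io.StringIO(TOY_GTF), dialect="gtf")


@pytest.fixture(scope="session")
def toy_index(toy_genes):
    return GenomeIndex(toy_genes)


@pytest.fixture()
def small_manifest():
    m = CohortManifest()
    for sid, ph, st in [("s1", "case", "AA"), ("s2", "case", "AA"),
                        ("s3", "case", "AA"), ("s4", "control", "AA"),
                        ("s5", "control", "AA"), ("s6", "control", "AA")]:
        m.add(sid, ph, st)
    return m


def make_aa_ea_manifest(n_aa_case=116, n_aa_ctrl=408, n_ea_case=89,
                        n_ea_ctrl=262):
    """Cohort with the stratum sizes of the study design being modeled."""
    m = CohortManifest()
    for i in range(n_aa_case):
        m.add(f"AA_case_{i:04d}", "case", "AA")
    for i in range(n_aa_ctrl):
        m.add(f"AA_ctrl_{i:04d}", "control", "AA")
    for i in range(n_ea_case):
        m.add(f"EA_case_{i:04d}", "case", "EA")
    for i in range(n_ea_ctrl):
        m.add(f"EA_ctrl_{i:04d}", "control", "EA")
    return m
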