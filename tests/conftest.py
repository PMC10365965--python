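import pysam
import pytest

from ctcdx.synthetic_data import (
    default_truth,
    deterministic_cohort,
    gen_read_set,
    gen_variant_calls,
)


@pytest.fixture(scope="session")
def truth():
    """The standard sequencing fixture: somatics + germline + 8 artifacts."""
    return default_truth(seed=11)


@pytest.fixture(scope="session")
def read_set(truth, tmp_path_factory):
    """SAM/FASTA written to disk and parsed back through pysam."""
    sam_text, fasta_text = gen_read_set(truth, depth_per_site=30,
                                        read_len=100, seed=11)
    d = tmp_path_factory.mktemp("readset")
    sam_path = d / "tumour.sam"
    sam_path.write_text(sam_text)
    (d / "reference.fa").write_text(fasta_text)
    with pysam.AlignmentFile(str(sam_path), "r") as af:
        reads = list(af)
    return {"reads": reads, "sam_path": sam_path,
            "fasta_path": d / "reference.fa", "sam_text": sam_text}


@pytest.fixture(scope="session")
def call_pair(truth):
    tumour, control = gen_variant_calls(truth, seed=11)
    return tumour, control


@pytest.fixture(scope="session")
def screening_cohort():
    """122-patient cohort with a designed 51/97 vs 5/25 2x2 at cutoff 2.5."""
    return deterministic_cohort(seed=5)


def make_read(pos0, seq, mapq=60, secondary=False, name="r0", cigar=None,
              contig_len=2000):
    """Construct a single aligned segment in memory (0-based start)."""
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"},
         "SQ": [{"SN": "chr_sim", "LN": contig_len}]}
    )
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = seq
    a.flag = 256 if secondary else 0
    a.reference_id = 0
    a.reference_start = pos0
    a.mapping_quality = mapq
    a.cigarstring = cigar or f"{len(seq)}M"
    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    return a
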