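"""Read- and variant-tier filter cascade: unit checks, pileup oracle,
published VAF arithmetic, truth recovery, order independence."""

import itertools
import math

import numpy as np
import pytest

from conftest import make_read
from ctcdx.errors import InputValidationError
from ctcdx.variant_filtering import (
    DEPTH,
    FLANK_MISMATCH,
    IN_CONTROL,
    LOW_MAPQ,
    LOW_VAF,
    POP_AF,
    SECONDARY,
    SHORT_FLANK,
    SYNONYMOUS,
    FilterConfig,
    VariantCall,
    allele_at,
    apply_cascade,
    flag_loh,
    read_passes,
    site_support,
)

CFG = FilterConfig()
RNG = np.random.default_rng(123)
REF = "".join(RNG.choice(list("ACGT"), size=2000))


def clean_read(pos, offset=50, length=100, alt=None, **kw):
    """Read covering 1-based ``pos`` at query ``offset`` with perfect flanks."""
    start = (pos - 1) - offset
    seq = list(REF[start:start + length])
    if alt is not None:
        seq[offset] = alt
    return make_read(start, "".join(seq), **kw)


class TestReadPasses:
    def test_clean_read_passes(self):
        ok, reasons = read_passes(clean_read(500), 500, REF, CFG)
        assert ok and not reasons

    def test_low_mapping_quality(self):
        ok, reasons = read_passes(clean_read(500, mapq=19), 500, REF, CFG)
        assert reasons == {LOW_MAPQ}
        ok, _ = read_passes(clean_read(500, mapq=20), 500, REF, CFG)
        assert ok  # boundary: "less than 20" excluded, 20 passes

    def test_secondary_alignment(self):
        _, reasons = read_passes(clean_read(500, secondary=True), 500, REF, CFG)
        assert reasons == {SECONDARY}

    def test_short_left_flank_at_offset_ten(self):
        # variant at read offset 10 of a 150 bp read: 10 < 20 left-flank bases
        _, reasons = read_passes(clean_read(500, offset=10, length=150),
                                 500, REF, CFG)
        assert reasons == {SHORT_FLANK}

    def test_flank_offsets_boundary(self):
        ok, _ = read_passes(clean_read(500, offset=20), 500, REF, CFG)
        assert ok  # exactly 20 bases on the left is enough
        _, reasons = read_passes(clean_read(500, offset=19), 500, REF, CFG)
        assert reasons == {SHORT_FLANK}
        # right flank: offset length-21 leaves exactly 20 on the right
        ok, _ = read_passes(clean_read(500, offset=79, length=100), 500, REF,
                            CFG)
        assert ok
        _, reasons = read_passes(clean_read(500, offset=80, length=100), 500,
                                 REF, CFG)
        assert reasons == {SHORT_FLANK}

    def test_flank_mismatch_detected_either_side(self):
        for delta in (-20, -1, 1, 20):
            read = clean_read(500)
            seq = list(read.query_sequence)
            qpos = 50 + delta
            seq[qpos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[qpos]]
            read.query_sequence = "".join(seq)
            _, reasons = read_passes(read, 500, REF, CFG)
            assert reasons == {FLANK_MISMATCH}, delta

    def test_mismatch_outside_flank_ignored(self):
        read = clean_read(500, offset=50, length=100)
        seq = list(read.query_sequence)
        seq[50 - 25] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[25]]
        read.query_sequence = "".join(seq)
        ok, _ = read_passes(read, 500, REF, CFG)
        assert ok

    def test_variant_base_itself_not_a_mismatch(self):
        ok, _ = read_passes(clean_read(500, alt="N"), 500, REF, CFG)
        assert ok

    def test_deletion_in_flank_counts_as_mismatch(self):
        start = 499 - 50
        seq = REF[start:start + 40] + REF[start + 41:start + 101]
        read = make_read(start, seq, cigar="40M1D60M")
        _, reasons = read_passes(read, 500, REF, CFG)
        assert FLANK_MISMATCH in reasons

    def test_insertion_in_flank_counts_as_mismatch(self):
        start = 499 - 50
        seq = REF[start:start + 40] + "A" + REF[start + 40:start + 99]
        read = make_read(start, seq, cigar="40M1I59M")
        _, reasons = read_passes(read, 500, REF, CFG)
        assert FLANK_MISMATCH in reasons

    def test_non_overlapping_read_rejected(self):
        with pytest.raises(InputValidationError, match="overlap"):
            read_passes(clean_read(500), 900, REF, CFG)

    def test_multiple_reasons_accumulate(self):
        _, reasons = read_passes(
            clean_read(500, offset=5, mapq=10, secondary=True), 500, REF, CFG
        )
        assert reasons == {LOW_MAPQ, SECONDARY, SHORT_FLANK}


def make_call(pos=500, alt="X", alt_reads=10, depth=25, **kw):
    if alt == "X":
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[REF[pos - 1]]
    vaf = alt_reads / depth if depth else 0.0
    return VariantCall(chrom="chr_sim", pos=pos, ref=REF[pos - 1], alt=alt,
                       alt_reads=alt_reads, depth=depth, vaf=vaf, **kw)


class TestSiteSupport:
    def test_published_style_ratio(self):
        # 16 qualifying alt reads of 24 total -> VAF 0.667
        reads = [clean_read(500, alt=None if i >= 16 else "X", name=f"r{i}",
                            offset=20 + i)
                 for i in range(24)]
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[REF[499]]
        for i in range(16):
            reads[i] = clean_read(500, alt=alt, name=f"r{i}", offset=20 + i)
        call = site_support(reads, make_call(alt_reads=16, depth=24), REF, CFG)
        assert (call.alt_reads, call.depth) == (16, 24)
        assert round(call.vaf, 3) == 0.667

    def test_disqualified_reads_match_pileup_oracle(self):
        reads = []
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[REF[499]]
        for i in range(30):
            mapq = 10 if i < 2 else 60
            secondary = i == 2
            reads.append(clean_read(500, alt=alt if i % 2 == 0 else None,
                                    mapq=mapq, secondary=secondary,
                                    name=f"r{i}", offset=20 + i % 50))
        call = site_support(reads, make_call(), REF, CFG)
        # oracle: brute-force pileup over individually re-checked reads
        keep = [r for r in reads
                if r.mapping_quality >= 20 and not r.is_secondary]
        assert call.depth == len(keep) == 27
        assert call.alt_reads == sum(
            1 for r in keep if allele_at(r, 500) == alt
        )

    def test_zero_alt_reads(self):
        reads = [clean_read(600, name=f"r{i}", offset=20 + i)
                 for i in range(50)]
        call = site_support(reads, make_call(pos=600, alt_reads=5, depth=50),
                            REF, CFG)
        assert call.alt_reads == 0 and call.vaf == 0.0
        assert LOW_VAF in call.filter_flags

    def test_zero_depth_leaves_vaf_undefined(self):
        call = site_support([], make_call(), REF, CFG)
        assert call.depth == 0 and math.isnan(call.vaf)
        assert DEPTH in call.filter_flags

    def test_failure_attributed_to_rescuing_read_filter(self):
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[REF[499]]
        reads = [clean_read(500, alt=alt if i < 12 else None, mapq=10,
                            name=f"r{i}", offset=20 + i) for i in range(30)]
        call = site_support(reads, make_call(alt_reads=12, depth=30), REF, CFG)
        assert call.filter_flags == {LOW_MAPQ}


def toy_tumour_table():
    """Six designed variants: exactly one clean somatic passes."""
    clean = make_call(pos=300, alt_reads=12, depth=30)
    low_vaf = make_call(pos=400, alt_reads=4, depth=30)
    pop = make_call(pos=500, alt_reads=12, depth=30,
                    pop_af={"EXAC": 0.02})
    in_ctrl = make_call(pos=600, alt_reads=15, depth=30)
    syn = make_call(pos=700, alt_reads=12, depth=30,
                    consequence="synonymous SNV")
    shallow = make_call(pos=800, alt_reads=8, depth=15)
    control = [make_call(pos=600, alt_reads=14, depth=28)]
    return [clean, low_vaf, pop, in_ctrl, syn, shallow], control


class TestApplyCascade:
    def test_hand_enumerated_toy_table(self):
        tumour, control = toy_tumour_table()
        flagged = apply_cascade(tumour, control, CFG)
        by_pos = {c.pos: c for c in flagged}
        assert by_pos[300].passed
        assert by_pos[400].filter_flags == {LOW_VAF}
        assert by_pos[500].filter_flags == {POP_AF}
        assert by_pos[600].filter_flags == {IN_CONTROL}
        assert by_pos[700].filter_flags == {SYNONYMOUS}
        assert by_pos[800].filter_flags == {DEPTH}
        assert sum(c.passed for c in flagged) == 1

    def test_every_removed_variant_carries_a_reason(self):
        tumour, control = toy_tumour_table()
        for call in apply_cascade(tumour, control, CFG):
            assert call.passed or call.filter_flags

    def test_variant_filter_order_independence(self):
        tumour, control = toy_tumour_table()
        reference = {
            c.key: frozenset(c.filter_flags)
            for c in apply_cascade(tumour, control, CFG)
        }
        # the pass set must not depend on the order filters are conceived in;
        # permute the *input rows* (flag accumulation is inherently unordered)
        for perm in itertools.permutations(range(len(tumour))):
            shuffled = [tumour[i] for i in perm]
            got = {
                c.key: frozenset(c.filter_flags)
                for c in apply_cascade(shuffled, control, CFG)
            }
            assert got == reference

    def test_in_control_requires_exact_allele_match(self):
        base = make_call(pos=600, alt_reads=15, depth=30)
        other_alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[REF[599]]
        control = [VariantCall(chrom="chr_sim", pos=600, ref=REF[599],
                               alt=other_alt, alt_reads=10, depth=20,
                               vaf=0.5)]
        flagged = apply_cascade([base], control, CFG)
        assert IN_CONTROL not in flagged[0].filter_flags

    def test_disable_unknown_code_rejected(self):
        with pytest.raises(InputValidationError, match="unknown filter"):
            apply_cascade([], [], CFG, disable=frozenset({"BOGUS"}))


class TestVafArithmeticAndLoh:
    # (sample, locus, alt_reads, other_reads, depth, printed VAF)
    PUBLISHED_ROWS = [
        ("P1", 7578115, 84, 0, 84, 1.0),
        ("P2", 7578115, 16, 8, 24, 0.667),
        ("P3", 7578115, 179, 0, 179, 1.0),
        ("P6", 7578115, 48, 1, 49, 0.980),
        ("P1", 7578645, 2028, 0, 2028, 1.0),
        ("P2", 7578645, 44, 68, 112, 0.393),
        ("P3", 7578645, 305, 0, 305, 1.0),
        ("P6", 7578645, 192, 1, 193, 0.995),
        ("P1", 7579472, 577, 1190, 1767, 0.327),
        ("P2", 7579472, 66, 59, 125, 0.528),
        ("P3", 7579472, 350, 1, 351, 0.997),
        ("P6", 7579472, 74, 0, 74, 1.0),
    ]

    @pytest.mark.parametrize("sample,pos,alt,other,depth,vaf", PUBLISHED_ROWS)
    def test_alt_over_depth_reproduces_reported_vaf(self, sample, pos, alt,
                                                    other, depth, vaf):
        assert alt + other == depth
        call = VariantCall(chrom="17", pos=pos, ref="N", alt="N",
                           alt_reads=alt, depth=depth, vaf=alt / depth)
        assert round(call.vaf, 3) == vaf

    def test_loh_flag_true_exactly_for_near_unit_vaf_rows(self):
        for sample, pos, alt, other, depth, vaf in self.PUBLISHED_ROWS:
            call = VariantCall(chrom="17", pos=pos, ref="N", alt="N",
                               alt_reads=alt, depth=depth, vaf=alt / depth)
            assert flag_loh(call, CFG) == (vaf >= 0.95)

    def test_loh_boundary_inclusive(self):
        call = VariantCall(chrom="1", pos=1, ref="A", alt="T", alt_reads=19,
                           depth=20, vaf=0.95)
        assert flag_loh(call, CFG)
        call = VariantCall(chrom="1", pos=1, ref="A", alt="T", alt_reads=327,
                           depth=1000, vaf=0.327)
        assert not flag_loh(call, CFG)


class TestFilterConfig:
    def test_invalid_thresholds_rejected(self):
        with pytest.raises(InputValidationError):
            FilterConfig(min_vaf=1.5)
        with pytest.raises(InputValidationError):
            FilterConfig(depth_basis="reads")

    def test_alt_depth_basis(self):
        call = make_call(pos=300, alt_reads=15, depth=40)
        flagged = apply_cascade([call], [],
                                FilterConfig(depth_basis="alt"))
        assert DEPTH in flagged[0].filter_flags  # 15 alt reads < 20

    def test_inconsistent_vaf_rejected(self):
        with pytest.raises(InputValidationError, match="inconsistent"):
            VariantCall(chrom="1", pos=1, ref="A", alt="T", alt_reads=5,
                        depth=10, vaf=0.9)
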