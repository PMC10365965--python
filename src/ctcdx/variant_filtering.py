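"""Somatic filter cascade with matched white-blood-cell subtraction.

Candidate variant calls from whole-genome-amplified CTC DNA are noisy;
this module implements a two-tier cleanup:

Read tier (per supporting read at the variant site):
  * LOW_MAPQ        — alignment quality below ``min_mapq`` (default 20)
  * SECONDARY       — secondary alignment
  * SHORT_FLANK     — fewer than ``flank_len`` (20) aligned bases on either
                      side of the variant position within the read
  * FLANK_MISMATCH  — any mismatch (or indel) against the reference within
                      the 20-base flank on either side, the variant position
                      itself excluded

Reads failing any check are disqualified; depth, alt count and VAF are then
recomputed from qualifying reads only.

Variant tier (per call, flag-based so removals stay auditable):
  * DEPTH       — qualifying depth below ``min_depth`` (20 reads)
  * LOW_VAF     — variant allele fraction below ``min_vaf`` (0.2)
  * POP_AF      — population allele frequency above ``max_pop_af`` (0.01)
                  in any of 1000Genomes / ESP6500 / in-house / ExAC
  * IN_CONTROL  — identical chrom/pos/ref/alt call in the matched
                  white-blood-cell control (germline subtraction), any VAF
  * SYNONYMOUS  — synonymous consequence

A call passes iff it carries no flags.  When read-tier disqualification is
what sinks a call, the failure is attributed to the single read filter whose
disabling alone would rescue it, so every removal carries the reason that
caused it.  Loss of heterozygosity is flagged when VAF >= ``loh_vaf``
(default 0.95, inclusive — "VAF approximately 1").

Coordinates are 1-based VCF convention throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pysam

from .errors import InputValidationError

# reason codes ---------------------------------------------------------------
LOW_MAPQ = "LOW_MAPQ"
SECONDARY = "SECONDARY"
SHORT_FLANK = "SHORT_FLANK"
FLANK_MISMATCH = "FLANK_MISMATCH"
DEPTH = "DEPTH"
LOW_VAF = "LOW_VAF"
POP_AF = "POP_AF"
IN_CONTROL = "IN_CONTROL"
SYNONYMOUS = "SYNONYMOUS"

READ_FILTERS = frozenset({LOW_MAPQ, SECONDARY, SHORT_FLANK, FLANK_MISMATCH})
VARIANT_FILTERS = frozenset({DEPTH, LOW_VAF, POP_AF, IN_CONTROL, SYNONYMOUS})
ALL_FILTERS = READ_FILTERS | VARIANT_FILTERS

POP_AF_DATABASES = ("1000G", "ESP6500", "INHOUSE", "EXAC")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the cascade; defaults are the published values."""

    min_mapq: int = 20
    flank_len: int = 20
    min_depth: int = 20
    min_vaf: float = 0.2
    max_pop_af: float = 0.01
    loh_vaf: float = 0.95
    #: "at least 20 reads" counts total qualifying depth; set to
    #: "alt" to require min_depth alt-supporting reads instead.
    depth_basis: str = "total"

    def __post_init__(self) -> None:
        if self.min_mapq < 0 or self.flank_len < 0 or self.min_depth < 0:
            raise InputValidationError("filter thresholds must be >= 0")
        if not 0.0 <= self.min_vaf <= 1.0 or not 0.0 <= self.loh_vaf <= 1.0:
            raise InputValidationError("VAF thresholds must lie in [0, 1]")
        if not 0.0 <= self.max_pop_af <= 1.0:
            raise InputValidationError("max_pop_af must lie in [0, 1]")
        if self.depth_basis not in ("total", "alt"):
            raise InputValidationError("depth_basis must be 'total' or 'alt'")


@dataclass
class VariantCall:
    """One candidate variant with read support, annotation and flags."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    alt_reads: int
    depth: int
    vaf: float
    pop_af: dict[str, float] = field(default_factory=dict)
    consequence: str = "non-synonymous"
    gene: str | None = None
    filter_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputValidationError(f"{self.key}: position must be 1-based")
        if not 0 <= self.alt_reads <= self.depth:
            raise InputValidationError(
                f"{self.key}: need 0 <= alt_reads <= depth, got "
                f"{self.alt_reads}/{self.depth}"
            )
        if self.depth > 0 and abs(self.vaf - self.alt_reads / self.depth) > 1e-6:
            raise InputValidationError(
                f"{self.key}: vaf {self.vaf} inconsistent with "
                f"{self.alt_reads}/{self.depth}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def passed(self) -> bool:
        return not self.filter_flags


def flag_loh(call: VariantCall, cfg: FilterConfig = FilterConfig()) -> bool:
    """Loss-of-heterozygosity flag: VAF >= loh_vaf (inclusive boundary)."""
    return not math.isnan(call.vaf) and call.vaf >= cfg.loh_vaf


# ---------------------------------------------------------------------------
# Read tier
# ---------------------------------------------------------------------------

def read_passes(
    read: pysam.AlignedSegment,
    pos: int,
    ref_seq: str,
    cfg: FilterConfig = FilterConfig(),
) -> tuple[bool, set[str]]:
    """Evaluate the four read-level checks for one read at a 1-based site.

    Returns ``(passes, reasons)``; the read must overlap ``pos`` on the
    reference (error otherwise).  SHORT_FLANK means the read simply does not
    extend ``flank_len`` aligned bases past the site; FLANK_MISMATCH means a
    base within the covered flank disagrees with the reference, or an indel
    interrupts the flank (strict reading of "no mismatches").
    """
    pos0 = pos - 1
    if read.is_unmapped or not (read.reference_start <= pos0 < read.reference_end):
        raise InputValidationError(
            f"read {read.query_name!r} does not overlap position {pos}"
        )
    reasons: set[str] = set()
    if read.mapping_quality < cfg.min_mapq:
        reasons.add(LOW_MAPQ)
    if read.is_secondary:
        reasons.add(SECONDARY)

    # map reference position -> (query position, read base)
    by_ref: dict[int, tuple[int | None, str | None]] = {}
    seq = read.query_sequence or ""
    for qpos, rpos in read.get_aligned_pairs():
        if rpos is not None:
            by_ref[rpos] = (qpos, seq[qpos] if qpos is not None else None)

    flank = cfg.flank_len
    window: list[int] = []  # query positions across flanks + site, for indel check
    for side in (range(pos0 - flank, pos0), range(pos0 + 1, pos0 + flank + 1)):
        for rpos in side:
            if rpos < read.reference_start or rpos >= read.reference_end:
                reasons.add(SHORT_FLANK)
                continue
            entry = by_ref.get(rpos)
            if entry is None or entry[0] is None or entry[1] is None:
                reasons.add(FLANK_MISMATCH)  # deletion inside the flank
                continue
            window.append(entry[0])
            if rpos >= len(ref_seq):
                raise InputValidationError(
                    f"position {rpos + 1} beyond reference length {len(ref_seq)}"
                )
            if entry[1].upper() != ref_seq[rpos].upper():
                reasons.add(FLANK_MISMATCH)
    # an insertion shifts query positions: covered flank+site query positions
    # must be consecutive when no clipping/indel interrupts them
    site = by_ref.get(pos0)
    if site is not None and site[0] is not None:
        window.append(site[0])
    if window and SHORT_FLANK not in reasons:
        window.sort()
        if window[-1] - window[0] != len(window) - 1:
            reasons.add(FLANK_MISMATCH)
    return (not reasons), reasons


def allele_at(read: pysam.AlignedSegment, pos: int) -> str | None:
    """Read base at a 1-based reference position; None across a deletion."""
    pos0 = pos - 1
    seq = read.query_sequence or ""
    for qpos, rpos in read.get_aligned_pairs():
        if rpos == pos0:
            return seq[qpos] if qpos is not None else None
    return None


# ---------------------------------------------------------------------------
# Variant tier
# ---------------------------------------------------------------------------

def _qualifying_support(
    reads, call: VariantCall, ref_seq: str, cfg: FilterConfig,
    ignore: frozenset[str],
) -> tuple[int, int]:
    """(depth, alt_reads) over reads surviving the non-ignored read checks."""
    depth = alt = 0
    for read in reads:
        pos0 = call.pos - 1
        if read.is_unmapped or not (
            read.reference_start <= pos0 < read.reference_end
        ):
            continue
        _, reasons = read_passes(read, call.pos, ref_seq, cfg)
        if reasons - ignore:
            continue
        base = allele_at(read, call.pos)
        if base is None:
            continue
        depth += 1
        if base.upper() == call.alt.upper():
            alt += 1
    return depth, alt


def site_support(
    reads,
    call: VariantCall,
    ref_seq: str,
    cfg: FilterConfig = FilterConfig(),
    *,
    disable: frozenset[str] = frozenset(),
) -> VariantCall:
    """Recompute a call's support from qualifying reads and set support flags.

    Returns a copy of ``call`` with ``alt_reads``/``depth``/``vaf`` replaced
    by the qualifying-read pileup and, when support is insufficient, a flag
    explaining why: the single read-filter code whose disabling would rescue
    the call (failure attribution), otherwise DEPTH and/or LOW_VAF from the
    fully filtered values.  ``disable`` names filter codes to skip (both
    read- and variant-tier codes are honoured).

    Zero qualifying depth leaves VAF undefined (NaN) with the DEPTH flag set.
    """
    reads = list(reads)
    ignored = frozenset(disable & READ_FILTERS)
    depth, alt = _qualifying_support(reads, call, ref_seq, cfg, ignored)
    vaf = alt / depth if depth > 0 else float("nan")

    def support_ok(d: int, a: int) -> bool:
        basis = d if cfg.depth_basis == "total" else a
        if DEPTH not in disable and basis < cfg.min_depth:
            return False
        if LOW_VAF not in disable:
            if d == 0 or (a / d) < cfg.min_vaf:
                return False
        return True

    flags: set[str] = set()
    if not support_ok(depth, alt):
        rescuers = []
        for code in sorted(READ_FILTERS - ignored):
            d2, a2 = _qualifying_support(
                reads, call, ref_seq, cfg, ignored | {code}
            )
            if support_ok(d2, a2):
                rescuers.append(code)
        if rescuers:
            flags.update(rescuers)
        else:
            basis = depth if cfg.depth_basis == "total" else alt
            if DEPTH not in disable and basis < cfg.min_depth:
                flags.add(DEPTH)
            if LOW_VAF not in disable and depth > 0 and vaf < cfg.min_vaf:
                flags.add(LOW_VAF)

    updated = replace(call, alt_reads=alt, depth=depth, vaf=vaf if depth else 0.0)
    updated.vaf = vaf  # keep NaN semantics for depth 0
    updated.filter_flags = set(call.filter_flags) | flags
    return updated


def apply_cascade(
    tumour: list[VariantCall],
    control: list[VariantCall],
    cfg: FilterConfig = FilterConfig(),
    *,
    reads=None,
    ref_seq: str | None = None,
    disable: frozenset[str] = frozenset(),
) -> list[VariantCall]:
    """Run the full somatic filter cascade over a tumour/control call pair.

    When ``reads`` (an iterable of aligned segments) and ``ref_seq`` are
    supplied, read-tier filtering and support recomputation run first;
    otherwise the calls' recorded depth/VAF are used.  Every applicable flag
    is accumulated (removal is flag-based, no silent drops), which makes the
    outcome independent of filter order.  ``disable`` switches off the named
    filters — used to audit which filter removes which call.

    Returns flagged copies of the tumour calls; a call passes iff its flag
    set is empty.
    """
    unknown = disable - ALL_FILTERS
    if unknown:
        raise InputValidationError(f"unknown filter codes: {sorted(unknown)}")
    if (reads is None) != (ref_seq is None):
        raise InputValidationError("reads and ref_seq must be given together")

    control_keys = {c.key for c in control}
    reads = list(reads) if reads is not None else None

    out: list[VariantCall] = []
    for call in tumour:
        if reads is not None:
            flagged = site_support(reads, call, ref_seq, cfg, disable=disable)
        else:
            flagged = replace(call)
            flagged.filter_flags = set(call.filter_flags)
            basis = flagged.depth if cfg.depth_basis == "total" else flagged.alt_reads
            if DEPTH not in disable and basis < cfg.min_depth:
                flagged.filter_flags.add(DEPTH)
            if LOW_VAF not in disable and (
                flagged.depth == 0 or flagged.vaf < cfg.min_vaf
            ):
                flagged.filter_flags.add(LOW_VAF)
        if POP_AF not in disable and any(
            af > cfg.max_pop_af for af in flagged.pop_af.values()
        ):
            flagged.filter_flags.add(POP_AF)
        if IN_CONTROL not in disable and flagged.key in control_keys:
            flagged.filter_flags.add(IN_CONTROL)
        if SYNONYMOUS not in disable and flagged.consequence.lower().startswith(
            "synonymous"
        ):
            flagged.filter_flags.add(SYNONYMOUS)
        out.append(flagged)
    return out
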