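"""Synthetic inputs with known truth for every pipeline stage.

Four generators emulate the upstream data the pipeline consumes:

* :func:`gen_cell_table` — candidate-cell morphology tables in which
  tumour-like cells are constructed to satisfy >= 4 diagnostic criteria and
  background cells (leukocytes, endothelial cells) <= 2, with the truth
  label stored per cell.
* :func:`gen_cohort` — per-patient CTC counts for a two-group cohort, from
  parametric count distributions or a deterministic mode that places an
  exact number of patients above/below a designed cutoff (so the 2x2 at the
  cutoff is exact by construction).
* :func:`gen_read_set` — a toy reference contig plus a valid SAM read set in
  which each designed true somatic variant has clean, deeply covered support
  and each designed artifact violates exactly one read-tier filter.
* :func:`gen_variant_calls` — the matching tumour/control VCF records with
  population-AF and consequence annotations, where each annotation-tier
  artifact carries exactly the annotation its filter targets.

All generators are deterministic under a fixed seed.  The read simulator
models only designed mismatches — no sequencing-error model, no
amplification bias, no FASTQ/alignment step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputValidationError
from .variant_filtering import (
    DEPTH,
    FLANK_MISMATCH,
    LOW_MAPQ,
    LOW_VAF,
    POP_AF,
    SECONDARY,
    SHORT_FLANK,
    SYNONYMOUS,
    VariantCall,
)

CONTIG = "chr_sim"

#: the eight artifact classes, one per filter the cascade must exercise
ARTIFACT_TAGS = (
    LOW_MAPQ,
    SECONDARY,
    SHORT_FLANK,
    FLANK_MISMATCH,
    DEPTH,
    LOW_VAF,
    POP_AF,
    SYNONYMOUS,
)

_BASES = "ACGT"


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in _BASES if b != base]
    return choices[int(rng.integers(len(choices)))]


# ---------------------------------------------------------------------------
# Cell tables
# ---------------------------------------------------------------------------

DEFAULT_CELL_PARAMS: dict[str, object] = {
    # how many criteria a tumour-like cell satisfies (always >= 4)
    "tumour_k_choices": (4, 5, 6),
    "tumour_k_probs": (0.5, 0.35, 0.15),
    # background cells satisfy at most 2 criteria by construction
    "background_k_choices": (0, 1, 2),
    "background_k_probs": (0.55, 0.35, 0.10),
    # abnormal nuclear division (override feature, not a criterion)
    "tumour_division_prob": 0.3,
}

_CRITERION_NAMES = (
    "abnormal_karyotype",       # c1
    "nc_ratio",                 # c2 (> 0.8)
    "diameter",                 # c3 (> 15 um)
    "hyperchromatic_uneven_nucleus",  # c4
    "irregular_nuclear_membrane",     # c5
    "large_nucleoli",           # c6
)


def gen_cell_table(
    n_tumour_like: int,
    n_background: int,
    feature_params: dict[str, object] | None = None,
    seed: int = 0,
    sample_id: str = "S1",
) -> pd.DataFrame:
    """Simulated candidate-cell morphology table with stored truth labels.

    For each cell a target number of satisfied criteria is drawn
    (tumour-like from ``tumour_k_choices``, background from
    ``background_k_choices``) and features are then constructed to satisfy
    exactly those criteria: diameter uniform in (15.5, 25) when c3 holds
    else (8, 14.5); ratio uniform in (0.82, 0.98) when c2 holds else
    (0.30, 0.78).  Background cells never carry abnormal nuclear division,
    so they cannot fire the override rule.
    """
    if n_tumour_like < 0 or n_background < 0:
        raise InputValidationError("cell counts must be >= 0")
    params = dict(DEFAULT_CELL_PARAMS)
    if feature_params:
        unknown = set(feature_params) - set(params)
        if unknown:
            raise InputValidationError(
                f"unknown cell feature parameters: {sorted(unknown)}"
            )
        params.update(feature_params)
    for which in ("tumour", "background"):
        probs = np.asarray(params[f"{which}_k_probs"], dtype=float)
        choices = params[f"{which}_k_choices"]
        if len(probs) != len(choices) or probs.min() < 0 or not math.isclose(
            probs.sum(), 1.0, abs_tol=1e-9
        ):
            raise InputValidationError(
                f"{which}_k_probs must be a probability vector matching "
                f"{which}_k_choices"
            )

    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_tumour_like + n_background):
        tumour_like = i < n_tumour_like
        which = "tumour" if tumour_like else "background"
        k = int(
            rng.choice(params[f"{which}_k_choices"],
                       p=params[f"{which}_k_probs"])
        )
        met = set(rng.choice(6, size=k, replace=False).tolist())
        row: dict[str, object] = {
            "cell_id": f"cell{i:04d}",
            "sample_id": sample_id,
            "diameter_um": round(
                float(rng.uniform(15.5, 25.0) if 2 in met
                      else rng.uniform(8.0, 14.5)), 2
            ),
            "nc_ratio": round(
                float(rng.uniform(0.82, 0.98) if 1 in met
                      else rng.uniform(0.30, 0.78)), 3
            ),
            "abnormal_karyotype": 0 in met,
            "hyperchromatic_uneven_nucleus": 3 in met,
            "irregular_nuclear_membrane": 4 in met,
            "large_nucleoli": 5 in met,
            "abnormal_nuclear_division": bool(
                tumour_like
                and rng.random() < float(params["tumour_division_prob"])
            ),
            "cluster_id": None,
            "is_tumour_like": tumour_like,
        }
        rows.append(row)
    columns = [
        "cell_id", "sample_id", "diameter_um", "nc_ratio",
        "abnormal_karyotype", "hyperchromatic_uneven_nucleus",
        "irregular_nuclear_membrane", "large_nucleoli",
        "abnormal_nuclear_division", "cluster_id", "is_tumour_like",
    ]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSimParams:
    """Two-group cohort simulation parameters.

    A count distribution is ``(family, params)`` with family one of
    ``negative_binomial`` (params mean, dispersion), ``poisson`` (params
    lam) or ``deterministic`` (params n_above, above_value, below_value —
    places exactly ``n_above`` patients above the designed cutoff).
    Defaults: negative binomial, malignant mean 3.0 / benign mean 1.2,
    dispersion 1.0 — stipulated, as no per-patient counts are published.
    """

    n_malignant: int
    n_benign: int
    count_dist_malignant: tuple[str, dict[str, float]] = (
        "negative_binomial", {"mean": 3.0, "dispersion": 1.0}
    )
    count_dist_benign: tuple[str, dict[str, float]] = (
        "negative_binomial", {"mean": 1.2, "dispersion": 1.0}
    )
    designed_cutoff: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_malignant < 1 or self.n_benign < 1:
            raise InputValidationError("both group sizes must be >= 1")
        if self.designed_cutoff < 0:
            raise InputValidationError("designed_cutoff must be >= 0")


def _draw_counts(
    rng: np.random.Generator,
    n: int,
    dist: tuple[str, dict[str, float]],
    cutoff: float,
) -> np.ndarray:
    family, p = dist
    if family == "negative_binomial":
        mean, disp = float(p["mean"]), float(p["dispersion"])
        if mean <= 0 or disp <= 0:
            raise InputValidationError(
                "negative_binomial requires mean > 0 and dispersion > 0"
            )
        return rng.negative_binomial(disp, disp / (disp + mean), size=n)
    if family == "poisson":
        lam = float(p["lam"])
        if lam <= 0:
            raise InputValidationError("poisson requires lam > 0")
        return rng.poisson(lam, size=n)
    if family == "deterministic":
        n_above = int(p["n_above"])
        above = int(p.get("above_value", math.ceil(cutoff) + 1))
        below = int(p.get("below_value", max(0, math.floor(cutoff) - 1)))
        if not 0 <= n_above <= n:
            raise InputValidationError("n_above must lie in [0, group size]")
        if not (above > cutoff and below < cutoff):
            raise InputValidationError(
                "deterministic mode needs above_value > cutoff > below_value"
            )
        return np.array([above] * n_above + [below] * (n - n_above))
    raise InputValidationError(f"unknown count distribution family {family!r}")


#: Lung-RADS category frequencies by group (2/3/4A/4B/4X), clinical-cohort-like
_LUNG_RADS_P = {
    "malignant": (0.156, 0.156, 0.021, 0.188, 0.479),
    "benign": (0.292, 0.208, 0.125, 0.042, 0.333),
}
_SUBSOLID_P = {"malignant": 0.813, "benign": 0.417}


def gen_cohort(params: CohortSimParams) -> pd.DataFrame:
    """Simulated per-patient cohort table.

    Columns: patient_id, ctc_count (cells/5 mL), malignant, lung_rads,
    nodule_nature.  In deterministic mode the 2x2 at ``designed_cutoff``
    equals the requested table exactly.  ``DataFrame.attrs["degenerate"]``
    flags a cohort in which every patient has the same count.
    """
    rng = np.random.default_rng(params.seed)
    frames = []
    for group, n, dist in (
        ("malignant", params.n_malignant, params.count_dist_malignant),
        ("benign", params.n_benign, params.count_dist_benign),
    ):
        counts = _draw_counts(rng, n, dist, params.designed_cutoff)
        lr = rng.choice(
            ["2", "3", "4A", "4B", "4X"], size=n, p=_LUNG_RADS_P[group]
        )
        nodule = np.where(
            rng.random(n) < _SUBSOLID_P[group], "subsolid", "solid"
        )
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": [f"{group[0].upper()}{i:03d}" for i in range(n)],
                    "ctc_count": counts.astype(int),
                    "malignant": group == "malignant",
                    "lung_rads": lr,
                    "nodule_nature": nodule,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.attrs["degenerate"] = out["ctc_count"].nunique() == 1
    out.attrs["designed_cutoff"] = params.designed_cutoff
    return out


def deterministic_cohort(
    n_above_malignant: int = 51,
    n_malignant: int = 97,
    n_above_benign: int = 5,
    n_benign: int = 25,
    cutoff: float = 2.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohort whose 2x2 at ``cutoff`` is exact by construction.

    Defaults reproduce a 122-patient screening cohort operating at
    sensitivity 51/97 and specificity 20/25 with the half-integer cutoff
    2.5 cells/5 mL: counts are 4 above and 1 below, so 2.5 is the midpoint
    of the two observed count values.
    """
    return gen_cohort(
        CohortSimParams(
            n_malignant=n_malignant,
            n_benign=n_benign,
            count_dist_malignant=(
                "deterministic",
                {"n_above": n_above_malignant, "above_value": 4, "below_value": 1},
            ),
            count_dist_benign=(
                "deterministic",
                {"n_above": n_above_benign, "above_value": 4, "below_value": 1},
            ),
            designed_cutoff=cutoff,
            seed=seed,
        )
    )


# ---------------------------------------------------------------------------
# Read sets and variant calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArtifactSpec:
    """A designed filter-violating variant, tagged with the one filter that
    must remove it."""

    pos: int  # 1-based
    ref: str
    alt: str
    tag: str

    def __post_init__(self) -> None:
        if self.tag not in ARTIFACT_TAGS:
            raise InputValidationError(f"unknown artifact tag {self.tag!r}")


@dataclass(frozen=True)
class SeqSimTruth:
    """Designed truth for one tumour/control sequencing pair."""

    reference_seq: str
    true_somatic: tuple[tuple[int, str, str, float], ...]
    germline: tuple[tuple[int, str, str, float], ...] = ()
    artifacts: tuple[ArtifactSpec, ...] = ()

    def __post_init__(self) -> None:
        L = len(self.reference_seq)
        for pos, ref, _alt, vaf in self.true_somatic + self.germline:
            if not 1 <= pos <= L:
                raise InputValidationError(f"position {pos} outside contig")
            if not 0 < vaf <= 1:
                raise InputValidationError(f"VAF at {pos} must lie in (0, 1]")
            if self.reference_seq[pos - 1] != ref:
                raise InputValidationError(f"ref allele mismatch at {pos}")
        for a in self.artifacts:
            if not 1 <= a.pos <= L:
                raise InputValidationError(f"artifact position {a.pos} outside contig")
            if self.reference_seq[a.pos - 1] != a.ref:
                raise InputValidationError(f"ref allele mismatch at {a.pos}")
        positions = [p for p, *_ in self.true_somatic + self.germline] + [
            a.pos for a in self.artifacts
        ]
        if len(positions) != len(set(positions)):
            raise InputValidationError("variant positions must be distinct")


def default_truth(
    seed: int = 0,
    contig_len: int = 2000,
    n_somatic: int = 2,
    n_germline: int = 2,
    somatic_vaf: float = 0.4,
    include_loh_somatic: bool = True,
) -> SeqSimTruth:
    """The standard fixture: designed somatics + germline + all 8 artifacts.

    With ``include_loh_somatic`` one extra true somatic at VAF 1.0 models a
    locus under loss of heterozygosity.  Sites are spaced >= 100 bp apart on
    a random toy contig so that no site's reads reach a neighbouring site's
    flanks.
    """
    rng = np.random.default_rng(seed)
    ref = "".join(rng.choice(list(_BASES), size=contig_len))
    somatic_vafs = [somatic_vaf] * n_somatic + (
        [1.0] if include_loh_somatic else []
    )
    n_sites = len(somatic_vafs) + n_germline + len(ARTIFACT_TAGS)
    positions = [150 + 120 * i for i in range(n_sites)]
    if positions[-1] > contig_len - 150:
        raise InputValidationError("contig too short for the designed sites")
    it = iter(positions)
    somatic = tuple(
        (p := next(it), ref[p - 1], _other_base(rng, ref[p - 1]), v)
        for v in somatic_vafs
    )
    germline = tuple(
        (p := next(it), ref[p - 1], _other_base(rng, ref[p - 1]), 0.5)
        for _ in range(n_germline)
    )
    artifacts = tuple(
        ArtifactSpec(p := next(it), ref[p - 1], _other_base(rng, ref[p - 1]), tag)
        for tag in ARTIFACT_TAGS
    )
    return SeqSimTruth(
        reference_seq=ref,
        true_somatic=somatic,
        germline=germline,
        artifacts=artifacts,
    )


@dataclass(frozen=True)
class _SiteDesign:
    pos: int
    ref: str
    alt: str
    n_reads: int
    n_alt: int
    mapq: int = 60
    secondary: bool = False
    forced_offset: int | None = None     # variant offset within each read
    flank_mismatch_at: int | None = None  # 1-based ref position mismatched


def _site_designs(
    truth: SeqSimTruth, depth: int, flank: int = 20
) -> list[_SiteDesign]:
    designs = []
    for pos, ref, alt, vaf in truth.true_somatic + truth.germline:
        designs.append(
            _SiteDesign(pos, ref, alt, depth, int(round(vaf * depth)))
        )
    for a in truth.artifacts:
        kw: dict[str, object] = {}
        n, n_alt = depth, int(round(0.4 * depth))
        if a.tag == LOW_MAPQ:
            kw["mapq"] = 10
        elif a.tag == SECONDARY:
            kw["secondary"] = True
        elif a.tag == SHORT_FLANK:
            kw["forced_offset"] = flank // 2  # only 10 left-flank bases
        elif a.tag == FLANK_MISMATCH:
            kw["flank_mismatch_at"] = a.pos - flank // 4  # inside left flank
        elif a.tag == DEPTH:
            n = 12  # clean reads, but fewer than the 20-read floor
            n_alt = 5
        elif a.tag == LOW_VAF:
            n_alt = max(1, int(round(0.1667 * depth)))  # VAF ~ 0.167 < 0.2
        # POP_AF and SYNONYMOUS sites have clean reads; their trigger is
        # annotation-level and lives in the VCF records.
        designs.append(_SiteDesign(a.pos, a.ref, a.alt, n, n_alt, **kw))
    return designs


def gen_read_set(
    truth: SeqSimTruth,
    depth_per_site: int = 30,
    read_len: int = 100,
    seed: int = 0,
) -> tuple[str, str]:
    """Valid SAM 1.6 text plus the reference FASTA for a truth design.

    Every designed-somatic site receives ``depth_per_site`` primary MAPQ-60
    reads whose variant offset leaves >= 20 perfect flanking bases on both
    sides; the alt fraction matches the designed VAF (rounded to reads).
    Artifact sites receive reads violating exactly their tagged filter.
    Reads are coordinate-sorted; same seed, same byte stream.
    """
    flank = 20
    if read_len <= 2 * flank + 1:
        raise InputValidationError(
            f"read_len must exceed {2 * flank + 1} so mismatch-free "
            f"{flank}-bp flanks are constructible"
        )
    ref = truth.reference_seq
    L = len(ref)
    rng = np.random.default_rng(seed)
    records: list[tuple[int, str]] = []

    for site in _site_designs(truth, depth_per_site, flank):
        pos0 = site.pos - 1
        lo = max(pos0 + flank - (read_len - 1), 0)       # offset <= read_len-1-flank
        hi = min(pos0 - flank, L - read_len)             # offset >= flank
        if site.forced_offset is not None:
            start = pos0 - site.forced_offset
            if start < 0 or start + read_len > L:
                raise InputValidationError(
                    f"variant at {site.pos}: no read placement with offset "
                    f"{site.forced_offset}"
                )
            starts = [start] * site.n_reads
        else:
            if lo > hi:
                raise InputValidationError(
                    f"variant at {site.pos}: too close to the contig end for "
                    f"{flank}-bp flanks"
                )
            starts = rng.integers(lo, hi + 1, size=site.n_reads).tolist()
        for i, start in enumerate(starts):
            is_alt = i < site.n_alt
            seq = list(ref[start : start + read_len])
            offset = pos0 - start
            if is_alt:
                seq[offset] = site.alt
            if site.flank_mismatch_at is not None:
                mis0 = site.flank_mismatch_at - 1
                if start <= mis0 < start + read_len:
                    seq[mis0 - start] = _other_base(rng, ref[mis0])
            flag = 256 if site.secondary else 0
            fields = [
                f"r{site.pos}_{i:03d}",
                str(flag),
                CONTIG,
                str(start + 1),
                str(site.mapq),
                f"{read_len}M",
                "*",
                "0",
                "0",
                "".join(seq),
                "I" * read_len,
            ]
            records.append((start + 1, "\t".join(fields)))

    records.sort(key=lambda r: (r[0], r[1]))
    sam = "\n".join(
        ["@HD\tVN:1.6\tSO:coordinate", f"@SQ\tSN:{CONTIG}\tLN:{L}"]
        + [r[1] for r in records]
    ) + "\n"
    fasta = f">{CONTIG}\n" + "\n".join(
        ref[i : i + 70] for i in range(0, L, 70)
    ) + "\n"
    return sam, fasta


_GENE_CYCLE = ("TP53", "EGFR", "KRAS_LIKE1", "RYR1", "ATM", "RB1", "KEAP1",
               "STK11", "BRAF_LIKE1", "MET_LIKE1")
_CLEAN_POP_AF = 0.0001
# rare germline variant: population databases do not catch it, so the
# matched white-blood-cell subtraction is what must remove it
_GERMLINE_POP_AF = 0.001


def gen_variant_calls(
    truth: SeqSimTruth, seed: int = 0, depth_per_site: int = 30
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Tumour and matched-control call lists mirroring the caller's output.

    Depth/alt counts are the *raw* pileup of :func:`gen_read_set` (before
    read-tier filtering, as an upstream caller would report).  Germline
    variants appear in both lists; designed somatics only in the tumour,
    with population AF <= 0.01 and a non-synonymous consequence; each
    annotation-tier artifact carries exactly its triggering annotation.
    """
    rng = np.random.default_rng(seed)  # reserved for future stochastic fields
    del rng
    genes = list(_GENE_CYCLE)
    tumour: list[VariantCall] = []
    control: list[VariantCall] = []

    def make(pos, ref, alt, n, n_alt, pop_af, consequence, gene):
        return VariantCall(
            chrom=CONTIG, pos=pos, ref=ref, alt=alt,
            alt_reads=n_alt, depth=n, vaf=n_alt / n,
            pop_af={db: pop_af for db in ("1000G", "ESP6500", "INHOUSE", "EXAC")},
            consequence=consequence, gene=gene,
        )

    gi = 0
    for site in _site_designs(truth, depth_per_site):
        gene = genes[gi % len(genes)]
        gi += 1
        is_germline = any(site.pos == p for p, *_ in truth.germline)
        artifact = next((a for a in truth.artifacts if a.pos == site.pos), None)
        pop_af = _CLEAN_POP_AF
        consequence = "non-synonymous SNV"
        if is_germline:
            pop_af = _GERMLINE_POP_AF
        if artifact is not None:
            if artifact.tag == POP_AF:
                pop_af = 0.05  # above threshold in every database column
            elif artifact.tag == SYNONYMOUS:
                consequence = "synonymous SNV"
        call = make(site.pos, site.ref, site.alt, site.n_reads, site.n_alt,
                    pop_af, consequence, gene)
        tumour.append(call)
        if is_germline:
            control.append(
                make(site.pos, site.ref, site.alt, site.n_reads, site.n_alt,
                     pop_af, consequence, gene)
            )
    return tumour, control


# ---------------------------------------------------------------------------
# Multi-sample gene/locus sets for the cross-sample comparison stage
# ---------------------------------------------------------------------------

def gen_multisample_sets(seed: int = 0):
    """Eight-sample design for the cross-sample comparison stage.

    Six malignant and two benign samples; two malignant samples are given
    low coverage (fraction of target at >= 20x below the 0.3 default) so QC
    excludes them.  The four retained malignant samples share three designed
    TP53 loci (one at VAF ~1 per sample, an LOH signature) plus a designed
    shared gene set partially overlapping the benign samples; truth is
    returned alongside.
    """
    from .cohort_genomics import SampleVariantSet

    rng = np.random.default_rng(seed)
    tp53_loci = [
        ("chr17_sim", 7578115, "T", "C"),
        ("chr17_sim", 7578645, "C", "T"),
        ("chr17_sim", 7579472, "G", "C"),
    ]
    shared_genes = {f"SHARED{i}" for i in range(6)} | {"TP53", "RYR1"}
    benign_seen = {"SHARED0", "SHARED1"}  # shared but not exclusive
    samples = []
    for i, sid in enumerate(["P1", "P2", "P3", "P6"]):
        private = {f"PRIV_{sid}_{j}" for j in range(int(rng.integers(2, 5)))}
        vafs = {}
        for j, locus in enumerate(tp53_loci):
            vafs[locus] = 1.0 if j == i % 3 else float(rng.uniform(0.3, 0.7))
        samples.append(
            SampleVariantSet(
                sample_id=sid,
                group="malignant",
                variants=set(tp53_loci),
                genes=shared_genes | private,
                coverage_stats={"fraction_target_ge_20x": 0.62,
                                "mean_target_depth": 85.0},
                vaf=vafs,
            )
        )
    for sid in ("P4", "P5"):  # excluded by QC: low coverage
        samples.append(
            SampleVariantSet(
                sample_id=sid,
                group="malignant",
                variants=set(),
                genes={"NOISE1"},
                coverage_stats={"fraction_target_ge_20x": 0.08,
                                "mean_target_depth": 6.0},
            )
        )
    for sid in ("P7", "P8"):
        samples.append(
            SampleVariantSet(
                sample_id=sid,
                group="benign",
                variants=set(),
                genes=set(benign_seen) | {f"BEN_{sid}"},
                coverage_stats={"fraction_target_ge_20x": 0.55,
                                "mean_target_depth": 70.0},
            )
        )
    truth = {
        "shared_in_malignant": set(shared_genes),
        "exclusive_to_malignant": set(shared_genes) - benign_seen,
        "concordant_loci": set(tp53_loci),
        "excluded_samples": {"P4", "P5"},
    }
    return samples, truth
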