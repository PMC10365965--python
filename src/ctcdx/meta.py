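"""Fixed- and random-effect pooling of case-control 2x2 odds ratios.

Pools per-study odds ratios (e.g. carriage of a risk genotype in lung
cancer cases versus controls) by Mantel-Haenszel fixed effect (default,
the conventional choice for dichotomous outcomes), inverse-variance fixed
effect, or DerSimonian-Laird random effect.  Heterogeneity is summarised by
Cochran's Q and I^2 = max(0, (Q - df)/Q) x 100 for every method.

Per-study odds ratios use ad/bc with a Woolf log-scale standard error; the
Haldane-Anscombe 0.5 continuity correction is applied (and flagged) when
any cell is zero.  The Mantel-Haenszel pooled log-OR standard error is the
Robins-Breslow-Greenland estimator, which needs no zero-cell correction
unless a margin is empty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InputValidationError

Z95 = 1.959964

MANTEL_HAENSZEL_FIXED = "mantel_haenszel_fixed"
INVERSE_VARIANCE_FIXED = "inverse_variance_fixed"
DERSIMONIAN_LAIRD_RANDOM = "dersimonian_laird_random"
METHODS = (
    MANTEL_HAENSZEL_FIXED,
    INVERSE_VARIANCE_FIXED,
    DERSIMONIAN_LAIRD_RANDOM,
)


@dataclass(frozen=True)
class Study2x2:
    """One case-control study's exposed/unexposed counts.

    Layout: a = case_exposed, b = case_unexposed, c = control_exposed,
    d = control_unexposed; OR = ad/bc.
    """

    study_id: str
    case_exposed: int
    case_unexposed: int
    control_exposed: int
    control_unexposed: int

    def __post_init__(self) -> None:
        cells = (
            self.case_exposed,
            self.case_unexposed,
            self.control_exposed,
            self.control_unexposed,
        )
        if any(c < 0 for c in cells):
            raise InputValidationError(f"{self.study_id}: counts must be >= 0")
        if self.case_exposed + self.case_unexposed < 1:
            raise InputValidationError(f"{self.study_id}: no cases")
        if self.control_exposed + self.control_unexposed < 1:
            raise InputValidationError(f"{self.study_id}: no controls")

    @property
    def n(self) -> int:
        return (
            self.case_exposed
            + self.case_unexposed
            + self.control_exposed
            + self.control_unexposed
        )


@dataclass(frozen=True)
class StudyOR:
    study_id: str
    or_: float
    ci95: tuple[float, float]
    log_or: float
    se: float
    corrected: bool  # Haldane-Anscombe 0.5 applied


@dataclass(frozen=True)
class PooledResult:
    method: str
    or_pooled: float
    ci95: tuple[float, float]
    q_stat: float
    i2: float  # percent, in [0, 100]
    tau2: float
    studies: tuple[StudyOR, ...]
    weights: tuple[float, ...]  # normalised to sum 1


def study_or(s: Study2x2) -> StudyOR:
    """Single-study odds ratio ad/bc with Woolf 95% CI."""
    a, b, c, d = (
        s.case_exposed,
        s.case_unexposed,
        s.control_exposed,
        s.control_unexposed,
    )
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    log_or = math.log(or_)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return StudyOR(
        study_id=s.study_id,
        or_=or_,
        ci95=(math.exp(log_or - Z95 * se), math.exp(log_or + Z95 * se)),
        log_or=log_or,
        se=se,
        corrected=corrected,
    )


def _heterogeneity(per_study: list[StudyOR]) -> tuple[float, float, float]:
    """Cochran's Q (inverse-variance weights), I^2 percent and DL tau^2."""
    w = [1.0 / s.se**2 for s in per_study]
    y = [s.log_or for s in per_study]
    sw = sum(w)
    ybar = sum(wi * yi for wi, yi in zip(w, y)) / sw
    q = sum(wi * (yi - ybar) ** 2 for wi, yi in zip(w, y))
    df = len(per_study) - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    denom = sw - sum(wi**2 for wi in w) / sw
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    return q, i2, tau2


def pool(
    studies: list[Study2x2], method: str = MANTEL_HAENSZEL_FIXED
) -> PooledResult:
    """Pool 2x2 tables into a single odds ratio with a 95% CI.

    Mantel-Haenszel: OR = sum(a_i d_i / n_i) / sum(b_i c_i / n_i), CI via
    the Robins-Breslow-Greenland log-OR variance.  Inverse-variance and
    DerSimonian-Laird pool per-study log-ORs (0.5-corrected where a cell is
    zero).  Q/I^2/tau^2 are reported for every method.
    """
    if not studies:
        raise InputValidationError("meta-analysis requires >= 1 study")
    if method not in METHODS:
        raise InputValidationError(f"unknown method {method!r}; use {METHODS}")
    per_study = [study_or(s) for s in studies]
    if len(studies) == 1:
        q, i2, tau2 = 0.0, 0.0, 0.0
    else:
        q, i2, tau2 = _heterogeneity(per_study)

    if method == MANTEL_HAENSZEL_FIXED:
        R = sum(s.case_exposed * s.control_unexposed / s.n for s in studies)
        S = sum(s.case_unexposed * s.control_exposed / s.n for s in studies)
        if R == 0 or S == 0:
            raise InputValidationError(
                "Mantel-Haenszel pooling undefined: an exposure margin is empty"
            )
        or_pooled = R / S
        # Robins-Breslow-Greenland variance of log(OR_MH)
        sum_pr = sum_psqr = sum_qs = 0.0
        for s in studies:
            p = (s.case_exposed + s.control_unexposed) / s.n
            qq = (s.case_unexposed + s.control_exposed) / s.n
            r = s.case_exposed * s.control_unexposed / s.n
            t = s.case_unexposed * s.control_exposed / s.n
            sum_pr += p * r
            sum_psqr += p * t + qq * r
            sum_qs += qq * t
        var = (
            sum_pr / (2 * R**2) + sum_psqr / (2 * R * S) + sum_qs / (2 * S**2)
        )
        se = math.sqrt(var)
        raw_w = [
            s.case_unexposed * s.control_exposed / s.n for s in studies
        ]  # MH weights are proportional to b_i c_i / n_i
        log_pooled = math.log(or_pooled)
    else:
        if method == INVERSE_VARIANCE_FIXED:
            raw_w = [1.0 / s.se**2 for s in per_study]
        else:
            raw_w = [1.0 / (s.se**2 + tau2) for s in per_study]
        sw = sum(raw_w)
        log_pooled = (
            sum(w * s.log_or for w, s in zip(raw_w, per_study)) / sw
        )
        se = math.sqrt(1.0 / sw)
        or_pooled = math.exp(log_pooled)

    ci = (math.exp(log_pooled - Z95 * se), math.exp(log_pooled + Z95 * se))
    sw = sum(raw_w)
    return PooledResult(
        method=method,
        or_pooled=or_pooled,
        ci95=ci,
        q_stat=q,
        i2=i2,
        tau2=tau2,
        studies=tuple(per_study),
        weights=tuple(w / sw for w in raw_w),
    )
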