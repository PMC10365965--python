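"""Diagnostic efficacy statistics for a count-valued biomarker.

Given per-patient CTC counts and the postoperative pathology label, this
module builds the ROC curve, selects the operating cutoff by the Youden
index (J = sensitivity + specificity - 1), derives the 2x2 confusion matrix
and its summary metrics (sensitivity, specificity, PPV, NPV, per-group
malignancy rates), compares AUCs (DeLong for paired designs, a normal test
on Hanley-McNeil standard errors otherwise), fits a binary logistic model
for co-factors (nodule nature, Lung-RADS category, CTC positivity), and runs
the standard two-group tests (chi-squared for categorical data,
Mann-Whitney U for counts).

Positivity is always "score strictly greater than the cutoff"; cutoffs are
reported as midpoints between consecutive distinct observed scores, so over
integer counts a cutoff of 2.5 means "positive = 3 or more cells / 5 mL".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import InputValidationError

#: the Lung-RADS ordinal categories accepted in cohort tables
LUNG_RADS_LEVELS = ("2", "3", "4A", "4B", "4X")


# ---------------------------------------------------------------------------
# ROC construction
# ---------------------------------------------------------------------------

@dataclass
class RocCurve:
    """An empirical ROC curve with trapezoidal AUC and Hanley-McNeil CI.

    ``thresholds[i]`` is the positivity threshold giving operating point
    ``(fpr[i], sensitivity[i])`` under the rule "positive = score >=
    threshold"; the first point is (0, 0) and the last (1, 1).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    fpr: np.ndarray
    auc: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int
    scores: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)


def _validate_two_class(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise InputValidationError("scores and labels must be equal-length 1-D")
    if labels.all() or (~labels).all():
        raise InputValidationError(
            "ROC requires both classes present; got a single class"
        )
    return scores, labels


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Standard error of a trapezoidal AUC (Hanley & McNeil, 1982)."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def roc_curve(scores, labels) -> RocCurve:
    """Empirical ROC curve of a score against a binary label.

    One operating point per distinct score value plus the (0, 0) endpoint.
    The trapezoidal AUC equals the tie-corrected Mann-Whitney statistic
    U / (n_pos * n_neg) with ties contributing 1/2; the 95% CI uses the
    Hanley-McNeil standard error, clipped to [0, 1].
    """
    scores, labels = _validate_two_class(scores, labels)
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    se = hanley_mcneil_se(auc, n_pos, n_neg)
    ci = (max(0.0, auc - 1.959964 * se), min(1.0, auc + 1.959964 * se))
    return RocCurve(
        thresholds=thr,
        sensitivity=tpr,
        fpr=fpr,
        auc=auc,
        ci95=ci,
        n_pos=n_pos,
        n_neg=n_neg,
        scores=scores,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# Youden cutoff and the 2x2
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class YoudenResult:
    cutoff: float
    j: float
    sensitivity: float
    specificity: float


def youden_cutoff(scores, labels) -> YoudenResult:
    """Cutoff maximising J = sensitivity + specificity - 1.

    Candidate cutoffs are midpoints between consecutive distinct observed
    scores, plus one below the minimum and one above the maximum (the
    degenerate all-positive / all-negative rules).  Ties in J are broken
    toward the *lower* cutoff, i.e. the more sensitive operating point.
    """
    scores, labels = _validate_two_class(scores, labels)
    distinct = np.unique(scores)
    candidates = np.concatenate(
        ([distinct[0] - 1.0], (distinct[:-1] + distinct[1:]) / 2.0,
         [distinct[-1] + 1.0])
    )
    best: YoudenResult | None = None
    for cut in candidates:
        positive = scores > cut
        sens = float((positive & labels).sum() / labels.sum())
        spec = float((~positive & ~labels).sum() / (~labels).sum())
        j = sens + spec - 1.0
        if best is None or j > best.j + 1e-12:
            best = YoudenResult(float(cut), j, sens, spec)
    assert best is not None
    return best


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of a 2x2 diagnostic table (positive = score > cutoff)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InputValidationError("confusion-matrix counts must be >= 0")

    @property
    def n_malignant(self) -> int:
        return self.tp + self.fn

    @property
    def n_benign(self) -> int:
        return self.fp + self.tn


def confusion_at(scores, labels, cutoff: float) -> ConfusionMatrix:
    """The 2x2 table of the rule "positive = score > cutoff"."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    positive = scores > cutoff
    return ConfusionMatrix(
        tp=int((positive & labels).sum()),
        fp=int((positive & ~labels).sum()),
        fn=int((~positive & labels).sum()),
        tn=int((~positive & ~labels).sum()),
    )


def diagnostic_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Summary ratios of a 2x2 table.

    ``malignancy_rate_pos`` is the malignancy rate among test-positives
    (identical to PPV); ``malignancy_rate_neg`` is the malignancy rate among
    test-negatives (= 1 - NPV = fn / (fn + tn)).  A ratio with a zero
    denominator is reported as NaN (undefined), never as 0.
    """

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    sens = ratio(cm.tp, cm.tp + cm.fn)
    spec = ratio(cm.tn, cm.tn + cm.fp)
    ppv = ratio(cm.tp, cm.tp + cm.fp)
    npv = ratio(cm.tn, cm.tn + cm.fn)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
        "npv": npv,
        "malignancy_rate_pos": ppv,
        "malignancy_rate_neg": ratio(cm.fn, cm.fn + cm.tn),
    }


# ---------------------------------------------------------------------------
# AUC comparison
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Placement values of DeLong et al. (1988) for one score vector."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n          # one entry per positive
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m    # one entry per negative
    return auc, v10, v01


def compare_auc(
    scores_a, scores_b, labels, labels_b=None, *, paired: bool = True
) -> dict[str, float]:
    """Two-sided test of AUC(a) = AUC(b).

    Paired (default): both scores measured on the same patients; DeLong's
    covariance-based z test.  Unpaired: ``labels_b`` gives the second
    cohort's labels and the test is normal on the difference with
    Hanley-McNeil standard errors.

    Returns ``{"auc_a", "auc_b", "z", "p"}``.  Identical paired score
    vectors give p = 1.
    """
    if paired:
        if len(np.asarray(scores_a)) != len(np.asarray(scores_b)):
            raise InputValidationError(
                "paired comparison requires scores on the same patients"
            )
        scores_a, labels = _validate_two_class(scores_a, labels)
        scores_b, _ = _validate_two_class(scores_b, labels)
        auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
        auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
        m, n = len(v10_a), len(v01_a)
        s10 = np.cov(np.vstack([v10_a, v10_b]))
        s01 = np.cov(np.vstack([v01_a, v01_b]))
        var = (
            (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
            + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
        )
        diff = auc_a - auc_b
        if var <= 0:
            z = 0.0 if abs(diff) < 1e-12 else math.inf * np.sign(diff)
        else:
            z = diff / math.sqrt(var)
    else:
        if labels_b is None:
            raise InputValidationError("unpaired comparison requires labels_b")
        roc_a = roc_curve(scores_a, labels)
        roc_b = roc_curve(scores_b, labels_b)
        auc_a, auc_b = roc_a.auc, roc_b.auc
        se = math.sqrt(
            hanley_mcneil_se(auc_a, roc_a.n_pos, roc_a.n_neg) ** 2
            + hanley_mcneil_se(auc_b, roc_b.n_pos, roc_b.n_neg) ** 2
        )
        diff = auc_a - auc_b
        z = 0.0 if (se == 0 and diff == 0) else diff / se if se > 0 else math.inf
    p = 2.0 * stats.norm.sf(abs(z))
    return {"auc_a": float(auc_a), "auc_b": float(auc_b),
            "z": float(z), "p": float(min(p, 1.0))}


# ---------------------------------------------------------------------------
# Logistic co-factor model
# ---------------------------------------------------------------------------

def fit_logistic(
    features: pd.DataFrame,
    labels,
    *,
    reference: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Binary logistic regression reported as odds ratios with 95% CIs.

    Numeric and boolean columns enter as-is; object/categorical columns are
    dummy-coded against a reference level (``reference`` maps column name to
    level; default is the lexicographically first level — pass
    ``{"nodule_nature": "solid", "lung_rads": "2"}`` for the conventional
    clinical coding).  Returns a DataFrame indexed by term with columns
    ``or_``, ``ci_lo``, ``ci_hi``, ``p`` and a boolean ``separation``
    attribute flag in ``DataFrame.attrs``; under (quasi-)separation the
    affected CIs are reported as unbounded.
    """
    reference = reference or {}
    cols = []
    for name in features.columns:
        col = features[name]
        if col.dtype == bool or np.issubdtype(col.dtype, np.number):
            cols.append(col.astype(float).rename(name))
        else:
            levels = sorted(col.astype(str).unique())
            ref = reference.get(name, levels[0])
            if ref not in levels:
                raise InputValidationError(
                    f"reference level {ref!r} absent from column {name!r}"
                )
            for lev in levels:
                if lev == ref:
                    continue
                cols.append(
                    (col.astype(str) == lev).astype(float).rename(f"{name}[{lev}]")
                )
    design = sm.add_constant(pd.concat(cols, axis=1), has_constant="add")
    y = np.asarray(labels, dtype=float)

    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=False, maxiter=200)
        except Exception:  # perfect separation makes the Hessian singular
            separation = True
            res = sm.Logit(y, design).fit(disp=False, maxiter=500,
                                          method="bfgs")

    params = pd.Series(res.params, index=design.columns)
    try:
        bse = pd.Series(res.bse, index=design.columns)
    except Exception:
        bse = pd.Series(np.inf, index=design.columns)
    if not separation and (bse > 50).any():
        separation = True  # quasi-separation: absurd standard errors
    try:
        pvals = pd.Series(res.pvalues, index=design.columns)
    except Exception:
        pvals = pd.Series(np.nan, index=design.columns)

    z = 1.959964
    with np.errstate(over="ignore"):  # unbounded CIs under separation
        out = pd.DataFrame(
            {
                "or_": np.exp(params),
                "ci_lo": np.exp(params - z * bse),
                "ci_hi": np.exp(params + z * bse),
                "p": pvals,
            }
        ).drop(index="const")
    if separation:
        big = bse > 50
        out.loc[big.drop(index="const"), ["ci_lo", "ci_hi"]] = [0.0, np.inf]
    out.attrs["separation"] = separation
    return out


# ---------------------------------------------------------------------------
# Group tests
# ---------------------------------------------------------------------------

def group_tests(values, groups) -> dict[str, float | str]:
    """Two-group comparison with the conventional test for the data type.

    Numeric values: two-sided Mann-Whitney U.  Categorical values:
    chi-squared on the contingency table without continuity correction
    (pass ``values`` as strings/objects).  Returns
    ``{"test", "statistic", "p"}``.
    """
    values = pd.Series(values)
    groups = pd.Series(groups)
    if groups.nunique() != 2:
        raise InputValidationError("group_tests requires exactly two groups")
    if np.issubdtype(values.dtype, np.number) or values.dtype == bool:
        g1, g2 = (values[groups == g].astype(float) for g in groups.unique())
        stat, p = stats.mannwhitneyu(g1, g2, alternative="two-sided")
        return {"test": "mann_whitney_u", "statistic": float(stat), "p": float(p)}
    table = pd.crosstab(values, groups)
    stat, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return {"test": "chi2", "statistic": float(stat), "p": float(p)}


def chi2_2x2(a: int, b: int, c: int, d: int, *, correction: bool = False):
    """Chi-squared test of a 2x2 table given as [[a, b], [c, d]]."""
    stat, p, _, _ = stats.chi2_contingency(
        np.array([[a, b], [c, d]]), correction=correction
    )
    return {"test": "chi2", "statistic": float(stat), "p": float(p)}
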