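"""Rule-based identification and enumeration of circulating tumour cells (CTCs).

Candidate cells arrive as morphology feature records scored upstream by a
pathologist (bright-field microscopy after size-based enrichment); no image
processing happens here.  A cell is called a CTC when it satisfies at least
four of six diagnostic criteria, or when it shows an override feature (large
nucleoli or abnormal nuclear division) together with at least two of the
*other* criteria:

    c1  abnormal karyotype
    c2  nucleus-to-cell area ratio > 0.8   (strict)
    c3  cell diameter > 15 um              (strict)
    c4  hyperchromatic, unevenly stained nucleus
    c5  irregular (thickened/folded) nuclear membrane
    c6  large nucleoli

Cells sharing a ``cluster_id`` (when the cluster has >= 2 members) form a
circulating tumour microembolus (CTM), counted once per cluster; cluster
members are excluded from the single-cell CTC count.  Counts are per 5 mL of
whole blood by convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import InputValidationError

#: ratio above which the nucleus is called dominant (strict inequality)
NC_RATIO_THRESHOLD = 0.8
#: diameter in micrometres above which the cell is called large (strict)
DIAMETER_THRESHOLD_UM = 15.0
#: criteria met for a CTC call through the main rule
MAIN_RULE_MIN_CRITERIA = 4
#: other criteria required alongside an override feature
OVERRIDE_MIN_OTHER_CRITERIA = 2

_BOOL_FEATURES = (
    "abnormal_karyotype",
    "hyperchromatic_uneven_nucleus",
    "irregular_nuclear_membrane",
    "large_nucleoli",
    "abnormal_nuclear_division",
)


@dataclass(frozen=True)
class CellRecord:
    """One candidate cell's morphology features.

    ``nc_ratio`` is the nucleus-to-whole-cell area ratio, necessarily in
    [0, 1]; values above 1 are data errors and are rejected.
    ``abnormal_nuclear_division`` is an override feature only — it is not one
    of the six criteria.  ``cluster_id`` marks CTM membership.
    """

    cell_id: str
    sample_id: str
    diameter: float
    nc_ratio: float
    abnormal_karyotype: bool
    hyperchromatic_uneven_nucleus: bool
    irregular_nuclear_membrane: bool
    large_nucleoli: bool
    abnormal_nuclear_division: bool
    cluster_id: str | None = None

    def __post_init__(self) -> None:
        for field in ("diameter", "nc_ratio"):
            value = getattr(self, field)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                raise InputValidationError(
                    f"cell {self.cell_id!r}: missing value for {field!r}"
                )
        for field in _BOOL_FEATURES:
            if getattr(self, field) is None:
                raise InputValidationError(
                    f"cell {self.cell_id!r}: missing value for {field!r}"
                )
        if self.diameter <= 0:
            raise InputValidationError(
                f"cell {self.cell_id!r}: diameter must be > 0, got {self.diameter}"
            )
        if not 0.0 <= self.nc_ratio <= 1.0:
            raise InputValidationError(
                f"cell {self.cell_id!r}: nucleus/cell area ratio must lie in "
                f"[0, 1], got {self.nc_ratio}"
            )


@dataclass(frozen=True)
class CriterionVector:
    """The six diagnostic criteria evaluated for one cell."""

    c1_abnormal_karyotype: bool
    c2_nc_ratio: bool
    c3_diameter: bool
    c4_hyperchromatic: bool
    c5_irregular_membrane: bool
    c6_large_nucleoli: bool
    override_feature: bool

    @property
    def n_met(self) -> int:
        return sum(
            (
                self.c1_abnormal_karyotype,
                self.c2_nc_ratio,
                self.c3_diameter,
                self.c4_hyperchromatic,
                self.c5_irregular_membrane,
                self.c6_large_nucleoli,
            )
        )


def score_criteria(cell: CellRecord) -> CriterionVector:
    """Evaluate the six diagnostic criteria for one cell.

    Thresholds for c2 and c3 are strict: a ratio of exactly 0.8 or a
    diameter of exactly 15.0 um does not meet the criterion.
    """
    c6 = cell.large_nucleoli
    return CriterionVector(
        c1_abnormal_karyotype=cell.abnormal_karyotype,
        c2_nc_ratio=cell.nc_ratio > NC_RATIO_THRESHOLD,
        c3_diameter=cell.diameter > DIAMETER_THRESHOLD_UM,
        c4_hyperchromatic=cell.hyperchromatic_uneven_nucleus,
        c5_irregular_membrane=cell.irregular_nuclear_membrane,
        c6_large_nucleoli=c6,
        override_feature=c6 or cell.abnormal_nuclear_division,
    )


def classify_cell(cell: CellRecord) -> tuple[bool, str]:
    """Classify one cell as CTC / non-CTC and report which rule fired.

    Returns ``(is_ctc, reason)``.  ``reason`` is one of
    ``"main_rule_{n}_criteria"``, ``"override_large_nucleoli"``,
    ``"override_nuclear_division"`` or ``"below_threshold"``.

    The override clause requires two criteria *other than* the triggering
    feature: when large nucleoli (c6) triggers, two of c1–c5 are needed;
    abnormal nuclear division is not itself a criterion, so when it triggers
    any two of c1–c6 qualify.
    """
    vec = score_criteria(cell)
    n = vec.n_met
    if n >= MAIN_RULE_MIN_CRITERIA:
        return True, f"main_rule_{n}_criteria"
    if vec.c6_large_nucleoli and (n - 1) >= OVERRIDE_MIN_OTHER_CRITERIA:
        return True, "override_large_nucleoli"
    if cell.abnormal_nuclear_division and n >= OVERRIDE_MIN_OTHER_CRITERIA:
        return True, "override_nuclear_division"
    return False, "below_threshold"


def classify_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Classify every row of a cell feature table.

    Returns a copy with ``is_ctc`` and ``reason`` columns appended.  Column
    names follow :func:`ctcdx.io.read_cell_table`.
    """
    out = cells.copy()
    decisions = []
    for row in cells.itertuples(index=False):
        cell = _record_from_row(row)
        decisions.append(classify_cell(cell))
    out["is_ctc"] = [d[0] for d in decisions]
    out["reason"] = [d[1] for d in decisions]
    return out


def count_sample(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-sample CTC and CTM enumeration.

    ``ctc_count``: CTC-classified cells that are not members of a cluster
    with >= 2 cells.  ``ctm_count``: distinct clusters (>= 2 members)
    containing at least one CTC-classified cell.  A ``cluster_id`` carried by
    a single cell does not form a cluster; that cell counts as a singleton.

    Returns a DataFrame indexed by ``sample_id`` with columns
    ``ctc_count`` and ``ctm_count``.  Raises on duplicate ``cell_id`` within
    a sample.
    """
    if cells.empty:
        return pd.DataFrame(columns=["ctc_count", "ctm_count"]).rename_axis(
            "sample_id"
        )
    dupes = cells.duplicated(subset=["sample_id", "cell_id"])
    if dupes.any():
        bad = cells.loc[dupes, ["sample_id", "cell_id"]].iloc[0]
        raise InputValidationError(
            f"duplicate cell_id {bad.cell_id!r} in sample {bad.sample_id!r}"
        )
    if "is_ctc" not in cells.columns:
        cells = classify_table(cells)

    rows = {}
    for sample_id, grp in cells.groupby("sample_id", sort=True):
        cluster_sizes = grp["cluster_id"].value_counts(dropna=True)
        real_clusters = set(cluster_sizes[cluster_sizes >= 2].index)
        in_cluster = grp["cluster_id"].isin(real_clusters)
        ctc = int((grp["is_ctc"] & ~in_cluster).sum())
        ctm = int(grp.loc[grp["is_ctc"] & in_cluster, "cluster_id"].nunique())
        rows[sample_id] = {"ctc_count": ctc, "ctm_count": ctm}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")


def _record_from_row(row) -> CellRecord:
    cluster = getattr(row, "cluster_id", None)
    if cluster is not None and (
        (isinstance(cluster, float) and math.isnan(cluster)) or cluster == ""
    ):
        cluster = None
    return CellRecord(
        cell_id=str(row.cell_id),
        sample_id=str(row.sample_id),
        diameter=float(row.diameter_um),
        nc_ratio=float(row.nc_ratio),
        abnormal_karyotype=bool(row.abnormal_karyotype),
        hyperchromatic_uneven_nucleus=bool(row.hyperchromatic_uneven_nucleus),
        irregular_nuclear_membrane=bool(row.irregular_nuclear_membrane),
        large_nucleoli=bool(row.large_nucleoli),
        abnormal_nuclear_division=bool(row.abnormal_nuclear_division),
        cluster_id=None if cluster is None else str(cluster),
    )
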