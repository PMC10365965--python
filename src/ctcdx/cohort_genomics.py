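"""Cross-sample mutation-set comparison and pathway enrichment.

After per-sample somatic filtering, samples are compared at the gene and
locus level: coverage-based QC exclusion, genes shared by every malignant
sample, genes among those never seen in benign samples, loci present in all
malignant and absent from all benign samples (with per-sample VAF and LOH
annotation), presence of a user-supplied driver-gene panel, and
over-representation analysis of a gene list against GMT pathways
(one-sided Fisher exact test, Benjamini-Hochberg FDR).

Gene-level presence is defined as >= 1 passing variant in the gene;
multiplicity is ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputValidationError
from .variant_filtering import FilterConfig, VariantCall, flag_loh

Locus = tuple[str, int, str, str]


@dataclass
class SampleVariantSet:
    """One sequenced sample's passing variants and coverage summary."""

    sample_id: str
    group: str  # "malignant" | "benign"
    variants: set[Locus] = field(default_factory=set)
    genes: set[str] = field(default_factory=set)
    coverage_stats: dict[str, float] = field(default_factory=dict)
    #: per-locus VAF of passing calls, for concordance annotation
    vaf: dict[Locus, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("malignant", "benign"):
            raise InputValidationError(
                f"sample {self.sample_id!r}: group must be malignant/benign"
            )

    @classmethod
    def from_calls(
        cls,
        sample_id: str,
        group: str,
        calls: list[VariantCall],
        coverage_stats: dict[str, float] | None = None,
    ) -> "SampleVariantSet":
        """Build from flagged calls; only passing calls contribute."""
        passing = [c for c in calls if c.passed]
        return cls(
            sample_id=sample_id,
            group=group,
            variants={c.key for c in passing},
            genes={c.gene for c in passing if c.gene},
            coverage_stats=dict(coverage_stats or {}),
            vaf={c.key: c.vaf for c in passing},
        )


@dataclass
class GeneSetDB:
    """Named pathways over a background gene universe (GMT-sourced)."""

    pathways: dict[str, set[str]]
    background: set[str]

    def __post_init__(self) -> None:
        if not self.pathways:
            raise InputValidationError("gene-set database has no pathways")
        for name, genes in self.pathways.items():
            if not genes:
                raise InputValidationError(f"pathway {name!r} is empty")
            if not genes <= self.background:
                raise InputValidationError(
                    f"pathway {name!r} contains genes outside the background"
                )


# ---------------------------------------------------------------------------

def sample_qc(
    samples: list[SampleVariantSet],
    *,
    min_fraction_20x: float | None = 0.3,
    min_mean_depth: float | None = None,
) -> tuple[list[SampleVariantSet], list[SampleVariantSet]]:
    """Split samples into (included, excluded) by sequencing coverage.

    A sample is kept when ``fraction_target_ge_20x`` meets
    ``min_fraction_20x`` and/or ``mean_target_depth`` meets
    ``min_mean_depth`` (whichever thresholds are given; at least one must
    be).  The default fraction threshold 0.3 is a stipulated convention —
    low-coverage whole-genome-amplified CTC libraries below it are not
    comparable at the locus level.
    """
    if min_fraction_20x is None and min_mean_depth is None:
        raise InputValidationError("at least one QC threshold is required")
    included, excluded = [], []
    for s in samples:
        ok = True
        if min_fraction_20x is not None:
            frac = s.coverage_stats.get("fraction_target_ge_20x")
            if frac is None:
                raise InputValidationError(
                    f"sample {s.sample_id!r}: missing fraction_target_ge_20x"
                )
            ok &= frac >= min_fraction_20x
        if min_mean_depth is not None:
            mean = s.coverage_stats.get("mean_target_depth")
            if mean is None:
                raise InputValidationError(
                    f"sample {s.sample_id!r}: missing mean_target_depth"
                )
            ok &= mean >= min_mean_depth
        (included if ok else excluded).append(s)
    return included, excluded


def shared_exclusive_genes(
    samples: list[SampleVariantSet],
) -> dict[str, set[str]]:
    """Genes mutated in every malignant sample, and those never benign.

    ``shared_in_malignant`` = intersection of gene sets over malignant
    samples; ``exclusive_to_malignant`` = that intersection minus the union
    of benign gene sets.
    """
    malignant = [s for s in samples if s.group == "malignant"]
    benign = [s for s in samples if s.group == "benign"]
    if not malignant:
        raise InputValidationError("no malignant samples after QC")
    shared = set.intersection(*(set(s.genes) for s in malignant))
    benign_union = set().union(*(s.genes for s in benign)) if benign else set()
    return {
        "shared_in_malignant": shared,
        "exclusive_to_malignant": shared - benign_union,
    }


def locus_concordance(samples: list[SampleVariantSet]) -> pd.DataFrame:
    """Loci present in every malignant sample and absent from every benign.

    Matching is exact on (chrom, pos, ref, alt).  The result carries the
    per-malignant-sample VAF and LOH flag for each concordant locus; one row
    per locus-sample pair, empty when no locus is universally concordant.
    """
    malignant = [s for s in samples if s.group == "malignant"]
    benign = [s for s in samples if s.group == "benign"]
    if not malignant:
        raise InputValidationError("no malignant samples after QC")
    concordant = set.intersection(*(s.variants for s in malignant))
    for s in benign:
        concordant -= s.variants
    cfg = FilterConfig()
    rows = []
    for locus in sorted(concordant):
        chrom, pos, ref, alt = locus
        for s in malignant:
            vaf = s.vaf.get(locus, float("nan"))
            rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "sample_id": s.sample_id,
                    "vaf": vaf,
                    "loh": vaf >= cfg.loh_vaf,
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "sample_id", "vaf", "loh"]
    )


def driver_overlap(
    samples: list[SampleVariantSet], panel: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample x gene presence matrix restricted to a driver panel.

    Returns ``(matrix, counts)``: a boolean DataFrame (rows = panel genes,
    columns = sample ids, zero rows retained for genes absent everywhere)
    and per-gene malignant/benign presence counts.
    """
    matrix = pd.DataFrame(
        {
            s.sample_id: [g in s.genes for g in panel]
            for s in samples
        },
        index=pd.Index(panel, name="gene"),
        dtype=bool,
    )
    counts = pd.DataFrame(
        {
            "n_malignant": [
                sum(g in s.genes for s in samples if s.group == "malignant")
                for g in panel
            ],
            "n_benign": [
                sum(g in s.genes for s in samples if s.group == "benign")
                for g in panel
            ],
        },
        index=pd.Index(panel, name="gene"),
    )
    return matrix, counts


def enrich(gene_list: list[str], db: GeneSetDB) -> pd.DataFrame:
    """Pathway over-representation of a gene list.

    One-sided Fisher exact test (hypergeometric upper tail) per pathway on
    the 2x2 [[overlap, list-only], [pathway-only, neither]] over the GMT
    background, with Benjamini-Hochberg correction across tested pathways.
    Genes outside the background are dropped with a warning.  Sorted by p.
    """
    genes = set(gene_list)
    off = genes - db.background
    if off:
        warnings.warn(
            f"dropping {len(off)} gene(s) outside the background: "
            f"{sorted(off)[:5]}..."
        )
        genes &= db.background
    n_bg = len(db.background)
    n_list = len(genes)
    rows = []
    for name, members in db.pathways.items():
        k = len(genes & members)
        table = [
            [k, n_list - k],
            [len(members) - k, n_bg - len(members) - n_list + k],
        ]
        _, p = stats.fisher_exact(table, alternative="greater")
        rows.append(
            {"pathway": name, "overlap": k, "pathway_size": len(members),
             "p": float(p)}
        )
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values("p", kind="stable").reset_index(drop=True)
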