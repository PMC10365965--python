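"""End-to-end synthetic run: simulate -> classify -> diagnose -> filter ->
compare -> enrich, with a machine-readable summary.

Each stage writes its inputs/outputs under ``out_dir`` and nothing mutates
its inputs; the summary carries provenance (config hash, seed, package
version).  Deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__
from .cohort_genomics import (
    GeneSetDB,
    SampleVariantSet,
    driver_overlap,
    enrich,
    locus_concordance,
    sample_qc,
    shared_exclusive_genes,
)
from .config import PipelineConfig
from .diagnostics import confusion_at, diagnostic_metrics, roc_curve, youden_cutoff
from .io import (
    read_sam,
    read_vcf,
    write_cell_table,
    write_cohort_table,
    write_gmt,
    write_vcf,
)
from .morphology import classify_table, count_sample
from .synthetic_data import (
    CONTIG,
    CohortSimParams,
    default_truth,
    deterministic_cohort,
    gen_cell_table,
    gen_cohort,
    gen_multisample_sets,
    gen_read_set,
    gen_variant_calls,
)
from .variant_filtering import apply_cascade, flag_loh

log = logging.getLogger("ctcdx")

#: a small synthetic pathway annotation used by the end-to-end run
_SYNTH_PATHWAYS = {
    "calcium_signalling_like": {"RYR1", "RYR3", "PHKG1", "SHARED2", "SHARED3"},
    "cell_cycle_like": {"TP53", "ATM", "RB1", "SHARED4"},
    "background_only": {f"BG{i}" for i in range(10)},
}


def _synthetic_gmt() -> GeneSetDB:
    background = set().union(*_SYNTH_PATHWAYS.values()) | {
        f"SHARED{i}" for i in range(6)
    } | {f"FILLER{i}" for i in range(40)}
    return GeneSetDB(pathways={k: set(v) for k, v in _SYNTH_PATHWAYS.items()},
                     background=background)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage on synthetic data and return the summary dict."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    sim = config.simulate
    cfg = config.filter_config()

    # --- cells -------------------------------------------------------------
    cells = gen_cell_table(
        sim.n_tumour_cells, sim.n_background_cells, seed=seed
    )
    write_cell_table(cells, out_dir / "cells.tsv")
    calls = classify_table(cells)
    counts = count_sample(calls)
    cell_summary = {
        "n_cells": int(len(cells)),
        "n_ctc": int(calls["is_ctc"].sum()),
        "per_sample": {
            str(k): {"ctc_count": int(v["ctc_count"]),
                     "ctm_count": int(v["ctm_count"])}
            for k, v in counts.iterrows()
        },
    }

    # --- cohort diagnostics -------------------------------------------------
    if sim.deterministic_counts:
        cohort = deterministic_cohort(
            n_above_malignant=sim.n_above_malignant,
            n_malignant=sim.n_malignant,
            n_above_benign=sim.n_above_benign,
            n_benign=sim.n_benign,
            cutoff=sim.designed_cutoff,
            seed=seed,
        )
    else:
        cohort = gen_cohort(
            CohortSimParams(
                n_malignant=sim.n_malignant, n_benign=sim.n_benign,
                designed_cutoff=sim.designed_cutoff, seed=seed,
            )
        )
    write_cohort_table(cohort, out_dir / "cohort.tsv")
    scores = cohort["ctc_count"].to_numpy(float)
    labels = cohort["malignant"].to_numpy(bool)
    roc = roc_curve(scores, labels)
    youden = youden_cutoff(scores, labels)
    cm = confusion_at(scores, labels, youden.cutoff)
    metrics = diagnostic_metrics(cm)
    diag_summary = {
        "n_patients": int(len(cohort)),
        "auc": roc.auc,
        "auc_ci95": list(roc.ci95),
        "cutoff": youden.cutoff,
        "youden_j": youden.j,
        "confusion": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
        "metrics": metrics,
    }

    # --- variant filtering ---------------------------------------------------
    truth = default_truth(seed=seed)
    sam_text, fasta_text = gen_read_set(
        truth, depth_per_site=sim.depth_per_site, read_len=sim.read_len,
        seed=seed,
    )
    (out_dir / "tumour.sam").write_text(sam_text)
    (out_dir / "reference.fa").write_text(fasta_text)
    tumour_calls, control_calls = gen_variant_calls(
        truth, seed=seed, depth_per_site=sim.depth_per_site
    )
    contigs = {CONTIG: len(truth.reference_seq)}
    write_vcf(tumour_calls, contigs, out_dir / "tumour.vcf")
    write_vcf(control_calls, contigs, out_dir / "control.vcf")
    # consume through the readers so the round trip is exercised end to end
    reads = read_sam(out_dir / "tumour.sam")
    tumour_in = read_vcf(out_dir / "tumour.vcf")
    control_in = read_vcf(out_dir / "control.vcf")
    flagged = apply_cascade(
        tumour_in, control_in, cfg, reads=reads,
        ref_seq=truth.reference_seq,
    )
    write_vcf(flagged, contigs, out_dir / "filtered.vcf")
    somatic_pos = {p for p, *_ in truth.true_somatic}
    passed = [c for c in flagged if c.passed]
    filt_summary = {
        "n_candidates": len(flagged),
        "n_pass": len(passed),
        "recovered_designed_somatics": sorted(c.pos for c in passed)
        == sorted(somatic_pos),
        "n_loh": sum(flag_loh(c, cfg) for c in flagged),
        "flags": {
            f"{c.chrom}:{c.pos}": sorted(c.filter_flags) for c in flagged
        },
    }

    # --- cross-sample comparison --------------------------------------------
    samples, set_truth = gen_multisample_sets(seed=seed)
    included, excluded = sample_qc(
        samples,
        min_fraction_20x=config.qc.min_fraction_20x,
        min_mean_depth=config.qc.min_mean_depth,
    )
    sets = shared_exclusive_genes(included)
    loci = locus_concordance(included)
    panel = ["TP53", "EGFR", "RYR1", "KRAS_LIKE1"]
    _, driver_counts = driver_overlap(included, panel)
    genomics_summary = {
        "n_sequenced": len(samples),
        "n_included": len(included),
        "excluded": sorted(s.sample_id for s in excluded),
        "n_shared_in_malignant": len(sets["shared_in_malignant"]),
        "n_exclusive_to_malignant": len(sets["exclusive_to_malignant"]),
        "n_concordant_loci": int(loci[["chrom", "pos"]].drop_duplicates().shape[0]),
        "n_loh_flagged_rows": int(loci["loh"].sum()),
        "driver_counts": driver_counts.to_dict(orient="index"),
    }

    # --- enrichment ----------------------------------------------------------
    db = _synthetic_gmt()
    write_gmt(db, out_dir / "pathways.gmt")
    gene_list = sorted(
        sets["exclusive_to_malignant"] & db.background
    )
    enr = enrich(gene_list, db) if gene_list else None
    enrich_summary = (
        {
            "n_genes_tested": len(gene_list),
            "top_pathway": enr.iloc[0]["pathway"],
            "top_p": float(enr.iloc[0]["p"]),
            "top_q": float(enr.iloc[0]["q"]),
        }
        if enr is not None
        else {"n_genes_tested": 0}
    )
    if enr is not None:
        enr.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)

    summary = {
        "provenance": {
            "version": __version__,
            "seed": seed,
            "config_hash": config.config_hash(),
        },
        "cells": cell_summary,
        "diagnostics": diag_summary,
        "variant_filtering": filt_summary,
        "cohort_genomics": genomics_summary,
        "enrichment": enrich_summary,
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                     sort_keys=True) + "\n")
    log.info("pipeline complete: %s", out_dir / "summary.json")
    return summary
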