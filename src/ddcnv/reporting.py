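"""Run summaries and end-to-end pipeline orchestration.

``summarize_run`` produces the per-assay accounting a digital-PCR
publication reports: mean +/- SEM droplets per well, samples genotyped
vs excluded (with one-decimal percentages), the fraction of samples
measured more than once and the concordance of those repeats.

``run_pipeline`` chains the whole analysis deterministically under one
master seed:

    simulate cohort -> simulate wells -> quantify -> call ->
    frequency table -> logistic association -> Wilcoxon tests -> report

writing every intermediate artifact (cohort CSV, wells CSV, estimates
TSV, calls TSV) plus a JSON report and a plain-text summary.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import association, cnv_calling, cohort_design, quantification, synthetic_data
from .cnv_calling import STATUS_CALLED, CopyNumberCall
from .quantification import DropletWell
from .synthetic_data import CohortSimConfig, WellSimConfig

__all__ = ["summarize_run", "run_pipeline", "DEFAULT_PIPELINE_CONFIG"]

logger = logging.getLogger("ddcnv")

#: A complete demonstration configuration: the default extreme cohort
#: genotyped for a hemizygous deletion with a single duplex assay, about
#: half the samples repeated in independent wells.
DEFAULT_PIPELINE_CONFIG: dict = {
    "cohort": {},  # CohortSimConfig defaults
    "assay": {
        "assay_id": "Hs01327571",
        "cnv_id": "esv27061",
        "n_droplets_mean": 13700,
        "n_droplets_sd": 1300,
        "lambda_reference": 0.5,
        "replicate_fraction": 0.48,
        "false_positive_rate": 0.0,
        "false_negative_rate": 0.0,
    },
    "association": {"covariates": ["age", "bmi", "sex"]},
}


def summarize_run(wells: Iterable[DropletWell],
                  calls: Iterable[CopyNumberCall]) -> pd.DataFrame:
    """Per-assay droplet statistics, exclusion accounting and concordance.

    Concordance is measured over samples with >= 2 measurement attempts:
    a repeated sample is concordant when every attempt resolved to the
    same integer call.
    """
    wells = list(wells)
    calls = list(calls)
    well_df = pd.DataFrame(
        [(w.assay_id, w.sample_id, w.replicate, w.n_droplets) for w in wells],
        columns=["assay_id", "sample_id", "replicate", "n_droplets"])

    rows = []
    for assay_id, adf in well_df.groupby("assay_id", sort=True):
        droplets = adf["n_droplets"].to_numpy(dtype=float)
        sem = 0.0 if droplets.size < 2 else float(
            droplets.std(ddof=1) / np.sqrt(droplets.size))
        assay_calls = [c for c in calls if c.assay_id == assay_id]
        n_attempted = len(assay_calls)
        n_genotyped = sum(c.status == STATUS_CALLED for c in assay_calls)
        n_excluded = n_attempted - n_genotyped

        reps_per_sample = adf.groupby("sample_id")["replicate"].nunique()
        repeated = reps_per_sample[reps_per_sample > 1].index
        concordant = 0
        for sample_id in repeated:
            sample_wells = [w for w in wells
                            if w.assay_id == assay_id and w.sample_id == sample_id]
            per_rep = {}
            for w in sample_wells:
                per_rep.setdefault(w.replicate, []).append(w)
            attempt_calls = [
                cnv_calling._attempt_from_wells(ws, max_cn=cnv_calling.DEFAULT_MAX_CN,
                                                confidence=0.95)
                for ws in per_rep.values()
            ]
            integers = {c.integer_call for c in attempt_calls}
            if len(integers) == 1 and None not in integers:
                concordant += 1
        rows.append(dict(
            assay_id=assay_id,
            droplets_mean=round(float(droplets.mean()), 1),
            droplets_sem=round(sem, 1),
            n_attempted=n_attempted,
            n_genotyped=n_genotyped,
            n_excluded=n_excluded,
            excluded_pct=cnv_calling.exclusion_rate(n_excluded, n_attempted)
            if n_attempted else 0.0,
            replicate_fraction=round(len(repeated) / len(reps_per_sample), 3)
            if len(reps_per_sample) else 0.0,
            concordance=round(concordant / len(repeated), 3) if len(repeated) else 1.0,
        ))
    return pd.DataFrame(rows)


def _simulate_wells_for_cohort(cohort: pd.DataFrame, assay_cfg: dict,
                               rng: np.random.Generator,
                               master_seed: int) -> list[DropletWell]:
    assay_id = assay_cfg.get("assay_id", "assay")
    n_mean = assay_cfg.get("n_droplets_mean", 13700)
    n_sd = assay_cfg.get("n_droplets_sd", 1300)
    lam_ref = assay_cfg.get("lambda_reference", 0.5)
    rep_frac = assay_cfg.get("replicate_fraction", 0.48)
    fp = assay_cfg.get("false_positive_rate", 0.0)
    fn = assay_cfg.get("false_negative_rate", 0.0)

    wells = []
    for row in cohort.itertuples(index=False):
        n_reps = 2 if rng.random() < rep_frac else 1
        for rep in range(1, n_reps + 1):
            n_droplets = max(1000, int(round(rng.normal(n_mean, n_sd))))
            cfg = WellSimConfig(n_droplets=n_droplets, lambda_reference=lam_ref,
                                true_cn=int(row.true_cn),
                                false_positive_rate=fp, false_negative_rate=fn)
            well_rng = np.random.default_rng(
                synthetic_data.derive_well_seed(master_seed, row.subject_id, rep))
            wells.append(synthetic_data.simulate_well(
                cfg, sample_id=row.subject_id, assay_id=assay_id,
                replicate=rep, rng=well_rng))
    return wells


def _retry_unresolved(calls: list[CopyNumberCall], cohort: pd.DataFrame,
                      wells: list[DropletWell], assay_cfg: dict,
                      master_seed: int,
                      rng: np.random.Generator) -> tuple[list[CopyNumberCall],
                                                         list[DropletWell]]:
    """Repeat single-attempt unresolved samples once, as bench practice."""
    true_cn = cohort.set_index("subject_id")["true_cn"]
    assay_id = assay_cfg.get("assay_id", "assay")
    resolved = []
    for call in calls:
        if call.status == STATUS_CALLED or call.n_repeats >= 2:
            resolved.append(call)
            continue
        n_droplets = max(1000, int(round(
            rng.normal(assay_cfg.get("n_droplets_mean", 13700),
                       assay_cfg.get("n_droplets_sd", 1300)))))
        cfg = WellSimConfig(
            n_droplets=n_droplets,
            lambda_reference=assay_cfg.get("lambda_reference", 0.5),
            true_cn=int(true_cn.loc[call.sample_id]),
            false_positive_rate=assay_cfg.get("false_positive_rate", 0.0),
            false_negative_rate=assay_cfg.get("false_negative_rate", 0.0))
        well_rng = np.random.default_rng(
            synthetic_data.derive_well_seed(master_seed, call.sample_id, 99))
        repeat = synthetic_data.simulate_well(
            cfg, sample_id=call.sample_id, assay_id=assay_id, replicate=2,
            rng=well_rng)
        wells.append(repeat)
        sample_wells = [w for w in wells
                        if w.sample_id == call.sample_id and w.assay_id == assay_id]
        resolved.extend(cnv_calling.call_wells(sample_wells))
    return resolved, wells


def run_pipeline(config: dict | None = None, out_dir: str | Path = "ddcnv_run",
                 seed: int = 0) -> dict:
    """Execute simulate -> quantify -> call -> associate -> report.

    Deterministic under ``seed``; returns the report dict and writes
    cohort.csv, wells.csv, estimates.tsv, calls.tsv, report.json and
    summary.txt under ``out_dir``.
    """
    config = {**DEFAULT_PIPELINE_CONFIG, **(config or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # --- stage 1: cohort -------------------------------------------------
    cohort_cfg = CohortSimConfig(**config.get("cohort", {}))
    cohort = synthetic_data.simulate_cohort(cohort_cfg, rng=rng)
    synthetic_data.cohort_to_csv(cohort, out / "cohort.csv")
    logger.info("stage cohort: %d subjects (%d high, %d low)", len(cohort),
                (cohort["group"] == "high").sum(), (cohort["group"] == "low").sum())

    # --- stage 2: droplet wells ------------------------------------------
    assay_cfg = config.get("assay", {})
    wells = _simulate_wells_for_cohort(cohort, assay_cfg, rng, seed)
    logger.info("stage wells: %d wells simulated", len(wells))

    # --- stage 3: quantification -----------------------------------------
    estimates = quantification.quantify_wells(wells)
    logger.info("stage quantify: %d channel estimates", len(estimates))

    # --- stage 4: calling (with a bench-style repeat of unresolved) ------
    calls = cnv_calling.call_wells(wells)
    calls, wells = _retry_unresolved(calls, cohort, wells, assay_cfg, seed, rng)
    quantification.wells_to_csv(wells, out / "wells.csv")
    estimates = quantification.quantify_wells(wells)
    quantification.estimates_to_tsv(estimates, out / "estimates.tsv")
    cnv_calling.calls_to_tsv(calls, out / "calls.tsv")
    n_called = sum(c.status == STATUS_CALLED for c in calls)
    logger.info("stage call: %d/%d samples genotyped", n_called, len(calls))

    # --- stage 5: association --------------------------------------------
    freq = association.build_frequency_table(calls, cohort)
    variant_cn = cohort_cfg.variant_cn
    carrier_of = {c.sample_id: int(c.integer_call == variant_cn)
                  for c in calls if c.status == STATUS_CALLED}
    genotyped = cohort[cohort["subject_id"].isin(carrier_of)].copy()
    genotyped["carrier"] = genotyped["subject_id"].map(carrier_of)

    tests_run = 0
    assoc_dict: dict | None = None
    if not freq.monomorphic:
        covariates = config.get("association", {}).get("covariates",
                                                       ["age", "bmi", "sex"])
        assoc = association.logistic_association(genotyped, "carrier", covariates)
        tests_run += 1
        assoc_dict = dict(
            odds_ratio=assoc.odds_ratio, or_ci_low=assoc.or_ci_low,
            or_ci_high=assoc.or_ci_high, beta=assoc.beta, beta_se=assoc.beta_se,
            p_value=assoc.p_value, covariates=list(assoc.covariates),
            n_high=assoc.n_high, n_low=assoc.n_low, status=assoc.status)

    wilcoxon: dict[str, dict] = {}
    if not freq.monomorphic:
        for group in ("high", "low"):
            gdf = genotyped[genotyped["group"] == group]
            carriers = gdf[gdf["carrier"] == 1]
            non = gdf[gdf["carrier"] == 0]
            if len(carriers) < 2 or len(non) < 2:
                continue
            for bp in ("sbp", "dbp"):
                stat, p = association.wilcoxon_bp_by_genotype(
                    carriers[bp].tolist(), non[bp].tolist())
                tests_run += 1
                wilcoxon[f"{group}_{bp}"] = dict(
                    rank_sum=stat, p_value=p,
                    n_carriers=len(carriers), n_noncarriers=len(non),
                    mean_diff_mmhg=round(float(carriers[bp].mean() - non[bp].mean()), 2))
    logger.info("stage associate: %d tests run", tests_run)

    # --- stage 6: report --------------------------------------------------
    run_summary = summarize_run(wells, calls)
    counts = freq.counts.copy()
    report = {
        "seed": seed,
        "assay_id": freq.assay_id,
        "cohort": {
            "n_high": int((cohort["group"] == "high").sum()),
            "n_low": int((cohort["group"] == "low").sum()),
        },
        "run_summary": run_summary.to_dict(orient="records"),
        "frequency_table": {
            "counts": {str(g): {str(cn): int(counts.loc[g, cn])
                                for cn in counts.columns}
                       for g in counts.index},
            "percentages": {str(g): {str(cn): float(freq.percentages().loc[g, cn])
                                     for cn in counts.columns}
                            for g in counts.index},
            "monomorphic": bool(freq.monomorphic),
        },
        "association": assoc_dict,
        "wilcoxon": wilcoxon,
        "n_tests_run": tests_run,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    _write_text_summary(report, out / "summary.txt")
    logger.info("stage report: written to %s", out)
    return report


def _write_text_summary(report: dict, path: Path) -> None:
    lines = [f"ddcnv pipeline report (seed {report['seed']})",
             f"assay: {report['assay_id']}", ""]
    for s in report["run_summary"]:
        lines.append(
            f"droplets/well {s['droplets_mean']} +/- {s['droplets_sem']} (SEM); "
            f"genotyped {s['n_genotyped']}/{s['n_attempted']} "
            f"(excluded {s['excluded_pct']}%); "
            f"repeated fraction {s['replicate_fraction']}, "
            f"concordance {s['concordance']}")
    lines.append("")
    lines.append("genotype counts (per group):")
    for group, row in report["frequency_table"]["counts"].items():
        pct = report["frequency_table"]["percentages"][group]
        cells = ", ".join(f"CN{cn}: {n} ({pct[cn]}%)" for cn, n in row.items())
        lines.append(f"  {group}: {cells}")
    if report["association"]:
        a = report["association"]
        if a["status"] == "converged":
            lines.append("")
            lines.append(
                f"logistic (high vs low ~ carrier + {'+'.join(a['covariates'])}): "
                f"OR {a['odds_ratio']:.2f} "
                f"[{a['or_ci_low']:.2f}, {a['or_ci_high']:.2f}], "
                f"P = {a['p_value']:.4f}")
        else:
            lines.append(f"logistic fit status: {a['status']}")
    for key, w in report["wilcoxon"].items():
        lines.append(
            f"Wilcoxon {key}: diff {w['mean_diff_mmhg']} mmHg, "
            f"P = {w['p_value']:.3f} "
            f"(n = {w['n_carriers']} vs {w['n_noncarriers']})")
    lines.append("")
    lines.append(f"tests run (unadjusted): {report['n_tests_run']}")
    path.write_text("\n".join(lines) + "\n")
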