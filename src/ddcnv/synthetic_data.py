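"""Synthetic ddPCR wells and extreme-blood-pressure cohorts.

Everything downstream of this module (quantification, integer calling,
cohort design, association) is exercised on data drawn here, so the
generator encodes the statistical structure the analysis assumes:

* **Wells.**  Template molecules land in droplets independently, so each
  droplet's occupancy is Poisson per channel: the reference channel at
  rate ``lambda_reference`` (the RNaseP two-copy locus) and the target
  channel at ``(true_cn / 2) * lambda_reference``.  A droplet reads
  positive when occupied, subject to optional per-droplet false-negative
  and false-positive rates (both default 0 — fluorescence "rain" is not
  modelled, only end-point counts).  Default well sizes and
  concentrations emulate runs of ~12,700-14,700 droplets carrying
  5,000-8,000 template copies per reaction (lambda around 0.4-0.6).

* **Cohorts.**  Two extreme SBP groups with per-group normal phenotype
  distributions, Bernoulli sex, Bernoulli antihypertensive treatment in
  the high group, and a group-dependent prevalence of the carrier copy
  number.  Defaults reproduce a 96-subject high / 92-subject low design
  (SBP 165.9 +/- 12.3 vs 98.6 +/- 5.2 mmHg, deletion prevalence 12.6% vs
  2.2%).

Seeds: every well's RNG seed derives from the master seed and a stable
hash of (sample, replicate), so plates are reproducible without seed
bookkeeping and wells are independent.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quantification import DropletWell

__all__ = [
    "WellSimConfig",
    "CohortSimConfig",
    "simulate_well",
    "simulate_plate",
    "simulate_cohort",
    "cohort_to_csv",
    "cohort_from_csv",
    "derive_well_seed",
]

COHORT_CSV_COLUMNS = ["subject_id", "group", "sbp", "dbp", "age", "sex",
                      "bmi", "treated", "true_cn"]


@dataclass(frozen=True)
class WellSimConfig:
    """Parameters of one simulated duplex well.

    ``lambda_target`` is always derived as ``(true_cn / 2) *
    lambda_reference`` — the two channels probe the same genomes, so the
    target concentration is fixed by the copy number.
    """

    n_droplets: int = 14_000
    lambda_reference: float = 0.5
    true_cn: int = 2
    false_positive_rate: float = 0.0
    false_negative_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_droplets <= 0:
            raise ValueError("n_droplets must be positive")
        if self.lambda_reference <= 0:
            raise ValueError("lambda_reference must be positive")
        if self.true_cn < 0:
            raise ValueError("true_cn must be a nonnegative integer")
        for name in ("false_positive_rate", "false_negative_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")

    @property
    def lambda_target(self) -> float:
        return (self.true_cn / 2.0) * self.lambda_reference


@dataclass(frozen=True)
class CohortSimConfig:
    """Two-group extreme-SBP cohort parameters (defaults: the studied design).

    ``variant_cn`` is the carrier genotype simulated at the per-group
    prevalence: 1 for a hemizygous deletion (default), 3 for a gain.
    Non-carriers are diploid (CN 2).
    """

    n_high: int = 96
    n_low: int = 92
    sbp_mean_high: float = 165.9
    sbp_sd_high: float = 12.3
    sbp_mean_low: float = 98.6
    sbp_sd_low: float = 5.2
    dbp_mean_high: float = 94.4
    dbp_sd_high: float = 10.8
    dbp_mean_low: float = 64.3
    dbp_sd_low: float = 7.2
    age_mean_high: float = 55.1
    age_sd_high: float = 8.3
    age_mean_low: float = 32.6
    age_sd_low: float = 14.5
    bmi_mean_high: float = 28.3
    bmi_sd_high: float = 4.5
    bmi_mean_low: float = 22.7
    bmi_sd_low: float = 3.2
    frac_male_high: float = 0.500
    frac_male_low: float = 0.511
    frac_treated_high: float = 0.531
    variant_prevalence_high: float = 0.126
    variant_prevalence_low: float = 0.022
    variant_cn: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_high < 0 or self.n_low < 0:
            raise ValueError("group sizes must be nonnegative")
        for name in ("sbp_sd_high", "sbp_sd_low", "dbp_sd_high", "dbp_sd_low",
                     "age_sd_high", "age_sd_low", "bmi_sd_high", "bmi_sd_low"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("frac_male_high", "frac_male_low", "frac_treated_high",
                     "variant_prevalence_high", "variant_prevalence_low"):
            frac = getattr(self, name)
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.variant_cn < 0:
            raise ValueError("variant_cn must be a nonnegative integer")


def derive_well_seed(master_seed: int, sample_id: str, replicate: int) -> int:
    """Stable per-well seed from the master seed and well identity."""
    digest = hashlib.sha256(
        f"{master_seed}|{sample_id}|{replicate}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def simulate_well(config: WellSimConfig, *, sample_id: str = "sample",
                  assay_id: str = "assay", well_id: str | None = None,
                  replicate: int = 1,
                  rng: np.random.Generator | None = None) -> DropletWell:
    """Draw one duplex well's droplet counts.

    Per-droplet occupancies are independent Poisson draws for each
    channel; a droplet is positive when occupied and not lost to a false
    negative, or when a false positive fires.  The same seed always
    reproduces the same counts.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_droplets

    def channel_positives(lam: float) -> int:
        positive = rng.poisson(lam, n) > 0
        if config.false_negative_rate > 0.0:
            positive &= rng.random(n) >= config.false_negative_rate
        if config.false_positive_rate > 0.0:
            positive |= rng.random(n) < config.false_positive_rate
        return int(positive.sum())

    k_target = channel_positives(config.lambda_target)
    k_reference = channel_positives(config.lambda_reference)
    return DropletWell(
        sample_id=sample_id, assay_id=assay_id,
        well_id=well_id if well_id is not None else f"{sample_id}-r{replicate}",
        replicate=replicate, n_droplets=n,
        k_target=k_target, k_reference=k_reference)


def simulate_plate(
    configs: Mapping[str, WellSimConfig] | Sequence[WellSimConfig],
    replicates: int = 1,
    *,
    master_seed: int = 0,
    assay_id: str = "assay",
) -> list[DropletWell]:
    """Simulate a plate: one config per sample, each run ``replicates`` times.

    ``configs`` may be a mapping sample_id -> config, or a sequence (ids
    are generated as S001, S002, ...).  Each well's seed derives
    deterministically from ``master_seed`` and its (sample, replicate)
    identity, so the full plate is reproducible and any well can be
    regenerated in isolation.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if isinstance(configs, Mapping):
        items = list(configs.items())
    else:
        items = [(f"S{i + 1:03d}", cfg) for i, cfg in enumerate(configs)]
    if not items:
        raise ValueError("simulate_plate requires at least one config")

    wells = []
    for sample_id, cfg in items:
        for rep in range(1, replicates + 1):
            rng = np.random.default_rng(derive_well_seed(master_seed, sample_id, rep))
            wells.append(simulate_well(cfg, sample_id=sample_id, assay_id=assay_id,
                                       replicate=rep, rng=rng))
    return wells


def _simulate_group(rng: np.random.Generator, cfg: CohortSimConfig,
                    group: str) -> list[dict]:
    hi = group == "high"
    n = cfg.n_high if hi else cfg.n_low
    mu = dict(
        sbp=(cfg.sbp_mean_high if hi else cfg.sbp_mean_low,
             cfg.sbp_sd_high if hi else cfg.sbp_sd_low),
        dbp=(cfg.dbp_mean_high if hi else cfg.dbp_mean_low,
             cfg.dbp_sd_high if hi else cfg.dbp_sd_low),
        age=(cfg.age_mean_high if hi else cfg.age_mean_low,
             cfg.age_sd_high if hi else cfg.age_sd_low),
        bmi=(cfg.bmi_mean_high if hi else cfg.bmi_mean_low,
             cfg.bmi_sd_high if hi else cfg.bmi_sd_low),
    )
    frac_male = cfg.frac_male_high if hi else cfg.frac_male_low
    frac_treated = cfg.frac_treated_high if hi else 0.0
    prevalence = cfg.variant_prevalence_high if hi else cfg.variant_prevalence_low

    subjects = []
    for i in range(n):
        # redraw until physiologically valid: sbp > dbp > 0, age >= 0, bmi > 0
        while True:
            sbp = rng.normal(*mu["sbp"])
            dbp = rng.normal(*mu["dbp"])
            age = rng.normal(*mu["age"])
            bmi = rng.normal(*mu["bmi"])
            if sbp > dbp > 0 and age >= 0 and bmi > 0:
                break
        subjects.append(dict(
            subject_id=f"{group.upper()}{i + 1:03d}",
            group=group,
            sbp=round(float(sbp), 2),
            dbp=round(float(dbp), 2),
            age=round(float(age), 1),
            sex="male" if rng.random() < frac_male else "female",
            bmi=round(float(bmi), 2),
            treated=int(rng.random() < frac_treated),
            true_cn=cfg.variant_cn if rng.random() < prevalence else 2,
        ))
    return subjects


def simulate_cohort(config: CohortSimConfig,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw an extreme two-group cohort as a tidy DataFrame.

    Columns: subject_id, group, sbp, dbp, age, sex, bmi, treated,
    true_cn.  Blood pressures are the measured (selected) phenotypes —
    treatment adjustment is downstream, in :mod:`ddcnv.cohort_design`.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = _simulate_group(rng, config, "high") + _simulate_group(rng, config, "low")
    return pd.DataFrame(rows, columns=COHORT_CSV_COLUMNS)


def cohort_to_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def cohort_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str, "sex": str})
    missing = set(COHORT_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df
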