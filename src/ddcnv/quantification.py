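"""Absolute quantification of template concentration from droplet counts.

In droplet digital PCR (ddPCR) a reaction is partitioned into ~10^4
nanolitre droplets, each read as positive or negative on two fluorescence
channels: a FAM-labelled target assay and a VIC-labelled reference assay
(RNaseP, a locus of known two-copy state).  Template molecules distribute
across droplets approximately Poisson, so the mean number of copies per
droplet is recovered from the observed positive fraction p = k/n:

    lambda_hat = -ln(1 - k/n)

This module estimates ``lambda`` per channel with a 95% confidence
interval, pools replicate wells at the droplet level (the merged-well
maximum-likelihood estimator), converts concentrations into copies per
reaction, and handles the reaction-sizing arithmetic that links genome
copies to DNA input mass.

Confidence intervals use a delta-method normal interval on ``lambda``
(SE = sqrt(p / (n (1-p)))) in the bulk regime, and fall back to an exact
binomial (Clopper-Pearson) interval on p transformed through -ln(1-p)
whenever the positive or negative droplet count is below
``EXACT_COUNT_THRESHOLD``.  Saturated wells (every droplet positive) have
no finite estimate and raise :class:`SaturatedWellError`.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "DropletWell",
    "ConcentrationEstimate",
    "ChannelEstimates",
    "ReactionCopies",
    "SaturatedWellError",
    "MalformedCountsError",
    "estimate_lambda",
    "merge_replicates",
    "copies_per_reaction",
    "dna_mass_for_copies",
    "quantify_wells",
    "wells_to_csv",
    "wells_from_csv",
    "estimates_to_tsv",
    "estimates_from_tsv",
]

#: Below this count of positive (or negative) droplets the delta-method
#: normal interval is unreliable; an exact binomial interval is used.
EXACT_COUNT_THRESHOLD = 5

#: Mass of one haploid human genome in picograms.
HAPLOID_GENOME_MASS_PG = 3.3

TARGET = "target"
REFERENCE = "reference"

WELL_CSV_COLUMNS = [
    "sample_id",
    "assay_id",
    "well_id",
    "replicate",
    "n_droplets",
    "k_target",
    "k_reference",
]

ESTIMATE_TSV_COLUMNS = [
    "sample_id",
    "assay_id",
    "replicate",
    "channel",
    "lambda",
    "ci_low",
    "ci_high",
    "k",
    "n",
    "wells_pooled",
    "status",
]


class SaturatedWellError(ValueError):
    """Every droplet positive: the Poisson estimator diverges."""


class MalformedCountsError(ValueError):
    """Droplet counts violate 0 <= k <= n, n > 0."""


@dataclass(frozen=True)
class DropletWell:
    """One well's droplet counts for a duplex (target + reference) assay."""

    sample_id: str
    assay_id: str
    well_id: str
    replicate: int
    n_droplets: int
    k_target: int
    k_reference: int

    def __post_init__(self) -> None:
        if self.n_droplets <= 0:
            raise MalformedCountsError(f"n_droplets must be positive, got {self.n_droplets}")
        for name, k in (("k_target", self.k_target), ("k_reference", self.k_reference)):
            if not 0 <= k <= self.n_droplets:
                raise MalformedCountsError(
                    f"{name}={k} outside [0, n_droplets={self.n_droplets}]"
                )

    def positives(self, channel: str) -> int:
        if channel == TARGET:
            return self.k_target
        if channel == REFERENCE:
            return self.k_reference
        raise ValueError(f"unknown channel {channel!r}")


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Mean copies per droplet (lambda) with a confidence interval.

    ``lambda_hat = -ln(1 - k/n)`` exactly, from counts pooled over
    ``wells_pooled`` wells.
    """

    lambda_hat: float
    ci_low: float
    ci_high: float
    k: int
    n: int
    wells_pooled: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci_low <= self.lambda_hat <= self.ci_high:
            raise ValueError(
                f"invalid interval ci_low={self.ci_low} <= lambda={self.lambda_hat}"
                f" <= ci_high={self.ci_high} violated"
            )


class ChannelEstimates(NamedTuple):
    target: ConcentrationEstimate
    reference: ConcentrationEstimate


class ReactionCopies(NamedTuple):
    """Template copies per reaction (lambda scaled by droplet count)."""

    copies: float
    ci_low: float
    ci_high: float


def estimate_lambda(k: int, n: int, *, confidence: float = 0.95,
                    wells_pooled: int = 1) -> ConcentrationEstimate:
    """Estimate mean copies per droplet from k positive of n droplets.

    Parameters
    ----------
    k, n
        Positive-droplet and total-droplet counts for one channel.
    confidence
        Two-sided confidence level for the interval (default 0.95).

    Raises
    ------
    SaturatedWellError
        If ``k == n`` (no finite estimate).
    MalformedCountsError
        If ``k > n``, ``k < 0`` or ``n <= 0``.
    """
    if n <= 0 or k < 0 or k > n:
        raise MalformedCountsError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    if k == n:
        raise SaturatedWellError(f"saturated well: k == n == {n}")

    p = k / n
    lam = -math.log1p(-p)
    z = norm.ppf(0.5 + confidence / 2.0)

    if k >= EXACT_COUNT_THRESHOLD and (n - k) >= EXACT_COUNT_THRESHOLD:
        # Delta method: Var(lambda_hat) = p / (n (1-p)).
        se = math.sqrt(p / (n * (1.0 - p)))
        lo = max(0.0, lam - z * se)
        hi = lam + z * se
    else:
        # Boundary regime: exact binomial interval on p, transformed.
        p_lo, p_hi = proportion_confint(k, n, alpha=1.0 - confidence, method="beta")
        lo = 0.0 if k == 0 else -math.log1p(-float(p_lo))
        hi = -math.log1p(-float(p_hi))

    return ConcentrationEstimate(lambda_hat=lam, ci_low=lo, ci_high=hi,
                                 k=k, n=n, wells_pooled=wells_pooled)


def merge_replicates(wells: Sequence[DropletWell], *,
                     confidence: float = 0.95) -> ChannelEstimates:
    """Pool replicate wells of one sample+assay and estimate both channels.

    Droplet counts are summed across wells before estimation (the
    merged-well estimator), which is the Poisson maximum-likelihood
    treatment of replicates; wells are never averaged per-well.
    """
    wells = list(wells)
    if not wells:
        raise ValueError("merge_replicates requires at least one well")
    samples = {w.sample_id for w in wells}
    assays = {w.assay_id for w in wells}
    if len(samples) > 1 or len(assays) > 1:
        raise ValueError(
            f"cannot pool wells across samples/assays: {sorted(samples)} x {sorted(assays)}"
        )
    n = sum(w.n_droplets for w in wells)
    estimates = []
    for channel in (TARGET, REFERENCE):
        k = sum(w.positives(channel) for w in wells)
        estimates.append(
            estimate_lambda(k, n, confidence=confidence, wells_pooled=len(wells))
        )
    return ChannelEstimates(*estimates)


def copies_per_reaction(est: ConcentrationEstimate, n_droplets: int) -> ReactionCopies:
    """Total template copies in a reaction of ``n_droplets`` partitions."""
    if n_droplets <= 0:
        raise ValueError("n_droplets must be positive")
    return ReactionCopies(
        copies=est.lambda_hat * n_droplets,
        ci_low=est.ci_low * n_droplets,
        ci_high=est.ci_high * n_droplets,
    )


def dna_mass_for_copies(target_copies: float,
                        mass_per_haploid_pg: float = HAPLOID_GENOME_MASS_PG) -> float:
    """DNA input mass in nanograms delivering ``target_copies`` haploid genomes.

    One haploid human genome weighs ~3.3 pg, so the ~10,000 copies needed
    per reaction for accurate ddPCR correspond to 33 ng of input DNA.
    """
    if target_copies < 0 or mass_per_haploid_pg < 0:
        raise ValueError("copies and mass must be nonnegative")
    return target_copies * mass_per_haploid_pg / 1000.0  # pg -> ng


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def quantify_wells(wells: Iterable[DropletWell], *, per_replicate: bool = True,
                   confidence: float = 0.95) -> pd.DataFrame:
    """Estimate lambda for every sample, assay and channel in a well table.

    With ``per_replicate=True`` (default) wells sharing a replicate index
    are pooled within that replicate; otherwise all wells of a sample+assay
    are pooled into a single merged estimate (replicate reported as 0).
    Saturated pools are reported with status ``saturated`` and no numeric
    estimate rather than an infinite value.
    """
    rows = []
    df_keys: dict[tuple, list[DropletWell]] = {}
    for w in wells:
        rep = w.replicate if per_replicate else 0
        df_keys.setdefault((w.sample_id, w.assay_id, rep), []).append(w)

    for (sample_id, assay_id, rep), group in sorted(df_keys.items()):
        n = sum(w.n_droplets for w in group)
        for channel in (TARGET, REFERENCE):
            k = sum(w.positives(channel) for w in group)
            try:
                est = estimate_lambda(k, n, confidence=confidence,
                                      wells_pooled=len(group))
                rows.append(
                    dict(sample_id=sample_id, assay_id=assay_id, replicate=rep,
                         channel=channel, **{"lambda": est.lambda_hat},
                         ci_low=est.ci_low, ci_high=est.ci_high, k=k, n=n,
                         wells_pooled=len(group), status="ok")
                )
            except SaturatedWellError:
                rows.append(
                    dict(sample_id=sample_id, assay_id=assay_id, replicate=rep,
                         channel=channel, **{"lambda": math.nan},
                         ci_low=math.nan, ci_high=math.nan, k=k, n=n,
                         wells_pooled=len(group), status="saturated")
                )
    return pd.DataFrame(rows, columns=ESTIMATE_TSV_COLUMNS)


def wells_to_csv(wells: Iterable[DropletWell], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(WELL_CSV_COLUMNS)
        for w in wells:
            writer.writerow([w.sample_id, w.assay_id, w.well_id, w.replicate,
                             w.n_droplets, w.k_target, w.k_reference])


def wells_from_csv(path: str | Path) -> list[DropletWell]:
    df = pd.read_csv(path, dtype={"sample_id": str, "assay_id": str, "well_id": str})
    missing = set(WELL_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"well CSV missing columns: {sorted(missing)}")
    return [
        DropletWell(sample_id=r.sample_id, assay_id=r.assay_id, well_id=r.well_id,
                    replicate=int(r.replicate), n_droplets=int(r.n_droplets),
                    k_target=int(r.k_target), k_reference=int(r.k_reference))
        for r in df.itertuples(index=False)
    ]


def estimates_to_tsv(estimates: pd.DataFrame, path: str | Path) -> None:
    estimates.to_csv(path, sep="\t", index=False)


def estimates_from_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "assay_id": str})
    missing = set(ESTIMATE_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"estimates TSV missing columns: {sorted(missing)}")
    return df
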