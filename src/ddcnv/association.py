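"""Association between copy-number genotype and extreme blood pressure.

Group-level statistics on resolved integer calls joined to cohort
phenotypes:

* genotype frequency tables per extreme group (carriers counted only
  among successfully genotyped subjects — excluded samples leave the
  denominator), with monomorphic loci flagged and skipped from testing;
* logistic regression of extreme-group membership (high = 1) on a
  carrier indicator, adjusted for age, BMI and sex, fit by Newton /
  iterated reweighted least squares with Wald intervals; complete
  separation is detected and reported as a status, never as a silently
  divergent estimate;
* unadjusted independent-sample (two-tailed) Wilcoxon rank-sum tests of
  BP by genotype within each group — exact by enumeration for small
  samples (n + m <= 12), normal approximation with midrank tie
  correction and continuity correction otherwise;
* descriptive side-by-side comparison of observed loss/gain frequencies
  against user-supplied reference-catalogue (DGV-style) frequencies.

No multiple-testing adjustment is applied; the report carries the number
of tests run so users can adjust externally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import mannwhitneyu, norm, rankdata
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .cnv_calling import STATUS_CALLED, CopyNumberCall

__all__ = [
    "FrequencyTable",
    "AssociationResult",
    "prevalence",
    "build_frequency_table",
    "logistic_association",
    "wilcoxon_bp_by_genotype",
    "compare_reference_frequencies",
]

#: Pooled sample size at or below which the Wilcoxon p-value is computed
#: by exhaustive enumeration of group labelings.
WILCOXON_EXACT_LIMIT = 12

STATUS_CONVERGED = "converged"
STATUS_SEPARATION = "separation"
STATUS_NOT_CONVERGED = "not_converged"


def prevalence(n_carriers: int, n_genotyped: int) -> float:
    """Carrier percentage among genotyped subjects, one-decimal reporting."""
    if n_genotyped <= 0:
        raise ValueError("n_genotyped must be positive")
    if not 0 <= n_carriers <= n_genotyped:
        raise ValueError("need 0 <= n_carriers <= n_genotyped")
    return round(100.0 * n_carriers / n_genotyped, 1)


@dataclass(frozen=True)
class FrequencyTable:
    """Genotype counts per extreme group for one assay/CNV.

    ``counts`` is indexed by group with one column per integer copy
    number; percentages are per-group (rows sum to 100 up to rounding).
    Monomorphic loci (a single copy-number class) are flagged so that no
    statistics are run on them.
    """

    assay_id: str
    counts: pd.DataFrame
    monomorphic: bool

    def percentages(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return (100.0 * self.counts.div(totals, axis=0)).round(1)

    def group_total(self, group: str) -> int:
        return int(self.counts.loc[group].sum())

    def carrier_counts(self, carrier_cn: int) -> pd.Series:
        if carrier_cn not in self.counts.columns:
            return pd.Series(0, index=self.counts.index)
        return self.counts[carrier_cn]

    def overall_variant_fraction(self) -> float:
        """Percentage of genotyped subjects with any non-diploid genotype."""
        total = int(self.counts.to_numpy().sum())
        variant = int(self.counts.drop(columns=[2], errors="ignore").to_numpy().sum())
        return prevalence(variant, total)


@dataclass(frozen=True)
class AssociationResult:
    """Covariate-adjusted logistic fit of group on carrier status."""

    odds_ratio: float
    or_ci_low: float
    or_ci_high: float
    beta: float
    beta_se: float
    p_value: float
    covariates: tuple[str, ...]
    n_high: int
    n_low: int
    status: str

    def __post_init__(self) -> None:
        if self.status == STATUS_CONVERGED:
            if not self.or_ci_low <= self.odds_ratio <= self.or_ci_high:
                raise ValueError("CI does not bracket the odds ratio")
            if not 0.0 <= self.p_value <= 1.0:
                raise ValueError("p-value outside [0, 1]")


def build_frequency_table(calls: Iterable[CopyNumberCall], cohort: pd.DataFrame,
                          assay_id: str | None = None) -> FrequencyTable:
    """Cross-tabulate resolved integer calls against extreme groups.

    Only ``called`` samples enter; excluded/failed samples are dropped
    from the denominators.  Calls must join to cohort rows by subject_id
    (orphan calls raise).
    """
    calls = list(calls)
    assays = {c.assay_id for c in calls}
    if assay_id is None:
        if len(assays) != 1:
            raise ValueError(f"calls span assays {sorted(assays)}; pass assay_id")
        assay_id = next(iter(assays))
    else:
        calls = [c for c in calls if c.assay_id == assay_id]
    if not calls:
        raise ValueError(f"no calls for assay {assay_id!r}")

    groups = cohort.set_index("subject_id")["group"]
    rows = []
    for c in calls:
        if c.status != STATUS_CALLED:
            continue
        if c.sample_id not in groups.index:
            raise ValueError(f"call for unknown subject {c.sample_id!r}")
        rows.append((groups.loc[c.sample_id], c.integer_call))
    if not rows:
        raise ValueError(f"no resolved calls for assay {assay_id!r}")
    df = pd.DataFrame(rows, columns=["group", "cn"])
    counts = (df.value_counts().unstack(fill_value=0)
              .sort_index(axis=0).sort_index(axis=1))
    counts.columns = counts.columns.astype(int)
    monomorphic = counts.shape[1] == 1
    return FrequencyTable(assay_id=assay_id, counts=counts, monomorphic=monomorphic)


def logistic_association(
    cohort: pd.DataFrame,
    genotype_col: str = "carrier",
    covariates: Sequence[str] = ("age", "bmi", "sex"),
    *,
    confidence: float = 0.95,
) -> AssociationResult:
    """Fit P(group == high) ~ carrier + covariates by maximum likelihood.

    ``sex`` is encoded male = 1.  Wald intervals on the carrier
    coefficient are exponentiated to the odds-ratio scale.  Perfect
    separation (all carriers in one group, MLE at infinity) is reported
    with status ``separation`` and no numeric estimate.
    """
    df = cohort.copy()
    y = (df["group"] == "high").astype(float)
    n_high, n_low = int(y.sum()), int((1 - y).sum())
    if n_high < 2 or n_low < 2:
        raise ValueError("need at least 2 subjects per group")

    X = pd.DataFrame(index=df.index)
    X[genotype_col] = df[genotype_col].astype(float)
    for cov in covariates:
        if cov == "sex":
            X["sex"] = (df["sex"] == "male").astype(float)
        else:
            X[cov] = df[cov].astype(float)
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant predictor(s): {constant}")
    X = sm.add_constant(X, prepend=True)

    def _result(status: str, beta=math.nan, se=math.nan, p=math.nan) -> AssociationResult:
        z = norm.ppf(0.5 + confidence / 2.0)
        if status == STATUS_CONVERGED:
            return AssociationResult(
                odds_ratio=math.exp(beta), or_ci_low=math.exp(beta - z * se),
                or_ci_high=math.exp(beta + z * se), beta=beta, beta_se=se,
                p_value=p, covariates=tuple(covariates),
                n_high=n_high, n_low=n_low, status=status)
        return AssociationResult(
            odds_ratio=math.nan, or_ci_low=math.nan, or_ci_high=math.nan,
            beta=beta, beta_se=se, p_value=math.nan,
            covariates=tuple(covariates), n_high=n_high, n_low=n_low, status=status)

    try:
        with warnings.catch_warnings(), np.errstate(over="ignore", divide="ignore"):
            warnings.simplefilter("ignore", category=PerfectSeparationWarning)
            warnings.simplefilter("ignore", category=RuntimeWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-10)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        # Newton hits a singular Hessian when the MLE walks to infinity
        return _result(STATUS_SEPARATION)
    if not fit.mle_retvals.get("converged", False):
        return _result(STATUS_NOT_CONVERGED)
    beta = float(fit.params[genotype_col])
    se = float(fit.bse[genotype_col])
    # near-separation: coefficient walking to infinity with huge SE
    if abs(beta) > 15 or se > 50:
        return _result(STATUS_SEPARATION)
    return _result(STATUS_CONVERGED, beta=beta, se=se,
                   p=float(fit.pvalues[genotype_col]))


def _exact_rank_sum_p(ranks: np.ndarray, n_a: int, w_obs: float) -> float:
    """Two-sided permutation p for the rank sum of group A by enumeration.

    Enumerates all C(N, n_a) assignments of the pooled midranks to group
    A; the two-sided p is the fraction of assignments whose rank sum
    deviates from its permutation mean at least as far as observed.
    """
    n_total = ranks.size
    mu = n_a * (n_total + 1) / 2.0
    dev_obs = abs(w_obs - mu) - 1e-9
    hits = total = 0
    for idx in combinations(range(n_total), n_a):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mu) >= dev_obs:
            hits += 1
    return hits / total


def wilcoxon_bp_by_genotype(values_a: Sequence[float],
                            values_b: Sequence[float]) -> tuple[float, float]:
    """Independent-sample two-tailed Wilcoxon rank-sum test.

    Returns ``(W, p)`` where W is the midrank sum of the first sample.
    Exact by enumeration when n + m <= 12; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    w = float(ranks[:a.size].sum())

    if np.ptp(pooled) == 0.0:  # all observations tied: no evidence either way
        return w, 1.0
    if a.size + b.size <= WILCOXON_EXACT_LIMIT:
        return w, _exact_rank_sum_p(ranks, a.size, w)
    p = float(mannwhitneyu(a, b, alternative="two-sided",
                           use_continuity=True, method="asymptotic").pvalue)
    return w, min(p, 1.0)


def compare_reference_frequencies(observed: pd.DataFrame,
                                  reference: pd.DataFrame) -> pd.DataFrame:
    """Observed vs reference-catalogue loss/gain percentages, descriptively.

    ``observed`` needs columns (cnv_id, loss_pct, gain_pct); ``reference``
    needs (cnv_id, loss_freq, gain_freq) as percentages.  Every observed
    CNV must have a reference row.  No test is performed — the output is
    a side-by-side table with absolute differences.
    """
    ref = reference.set_index("cnv_id")
    rows = []
    for r in observed.itertuples(index=False):
        if r.cnv_id not in ref.index:
            raise KeyError(f"no reference frequencies for CNV {r.cnv_id!r}")
        ref_row = ref.loc[r.cnv_id]
        rows.append(dict(
            cnv_id=r.cnv_id,
            observed_loss_pct=r.loss_pct, reference_loss_pct=float(ref_row["loss_freq"]),
            loss_diff=round(r.loss_pct - float(ref_row["loss_freq"]), 1),
            observed_gain_pct=r.gain_pct, reference_gain_pct=float(ref_row["gain_freq"]),
            gain_diff=round(r.gain_pct - float(ref_row["gain_freq"]), 1),
        ))
    return pd.DataFrame(rows)
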