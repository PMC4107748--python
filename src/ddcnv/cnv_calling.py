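"""Integer copy-number calling from duplex concentration estimates.

Copies per diploid genome are the reference-normalised ratio

    CN_hat = 2 * lambda_target / lambda_reference

since the reference assay (RNaseP) marks a locus present at exactly two
copies per diploid genome.  The confidence interval is propagated by the
delta method on log(lambda_t / lambda_r): the log-scale variances of the
two channel estimates are summed, the interval back-transformed and
doubled.

A sample is assigned an integer genotype by a CI-containment rule: the
95% interval of the measured CN must contain exactly one integer in the
call universe {1, 2, 3}.  Intervals containing no integer yield status
``no_integer`` (candidate mosaicism or degraded template); intervals
spanning two or more integers are ``ambiguous``.  Samples whose repeated
measurements never resolve to a consistent integer are ``excluded`` —
the repeat-and-exclude accounting that the exclusion-rate report
summarises.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import norm

from .quantification import (
    EXACT_COUNT_THRESHOLD,
    REFERENCE,
    TARGET,
    ConcentrationEstimate,
    DropletWell,
    merge_replicates,
)

__all__ = [
    "CopyNumberCall",
    "ReferenceFailureError",
    "cn_ratio",
    "call_integer",
    "resolve_sample",
    "exclusion_rate",
    "call_wells",
    "call_estimates_frame",
    "calls_to_frame",
    "calls_to_tsv",
    "calls_from_tsv",
]

STATUS_CALLED = "called"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_NO_INTEGER = "no_integer"
STATUS_FAILED = "failed_amplification"
STATUS_SATURATED = "saturated"
STATUS_EXCLUDED = "excluded"

#: Largest integer copy number in the default call universe.
DEFAULT_MAX_CN = 3

CALL_TSV_COLUMNS = ["sample_id", "assay_id", "cn_hat", "ci_low", "ci_high",
                    "call", "status", "n_repeats"]


class ReferenceFailureError(ValueError):
    """Reference channel unusable (no amplification or saturated)."""


@dataclass(frozen=True)
class CopyNumberCall:
    """Per-sample copy-number estimate with integer call or exclusion flag."""

    sample_id: str
    assay_id: str
    cn_hat: float
    ci_low: float
    ci_high: float
    integer_call: int | None
    status: str
    n_repeats: int = 1

    def __post_init__(self) -> None:
        if (self.integer_call is not None) != (self.status == STATUS_CALLED):
            raise ValueError("integer_call must be present iff status == 'called'")


def _log_scale_se(est: ConcentrationEstimate, z: float) -> float:
    """Standard error of log(lambda_hat).

    In the bulk regime this is SE(lambda)/lambda from the delta-method
    variance p/(n(1-p)); near the boundary (Clopper-Pearson interval) it
    is recovered from the interval's log-scale half-width.
    """
    if est.lambda_hat <= 0:
        raise ValueError("log-scale SE undefined for lambda == 0")
    if est.k >= EXACT_COUNT_THRESHOLD and (est.n - est.k) >= EXACT_COUNT_THRESHOLD:
        p = est.k / est.n
        se_lambda = math.sqrt(p / (est.n * (1.0 - p)))
        return se_lambda / est.lambda_hat
    return (math.log(est.ci_high) - math.log(est.ci_low)) / (2.0 * z)


def cn_ratio(target: ConcentrationEstimate, reference: ConcentrationEstimate,
             *, confidence: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Copies per diploid genome with a propagated confidence interval.

    Scale-invariant: multiplying both channel concentrations by a common
    factor leaves the ratio unchanged.  A target concentration of exactly
    zero yields CN 0 with a one-sided interval from the target's upper
    bound (the reference uncertainty is negligible against a zero
    numerator).

    Raises
    ------
    ReferenceFailureError
        If the reference concentration is zero.
    """
    if reference.lambda_hat <= 0:
        raise ReferenceFailureError("reference channel did not amplify (lambda == 0)")

    cn = 2.0 * target.lambda_hat / reference.lambda_hat
    if target.lambda_hat == 0.0:
        return 0.0, (0.0, 2.0 * target.ci_high / reference.lambda_hat)

    z = norm.ppf(0.5 + confidence / 2.0)
    se_log = math.hypot(_log_scale_se(target, z), _log_scale_se(reference, z))
    return cn, (cn * math.exp(-z * se_log), cn * math.exp(z * se_log))


def call_integer(cn_hat: float, ci: tuple[float, float], *,
                 sample_id: str = "", assay_id: str = "",
                 max_cn: int = DEFAULT_MAX_CN, n_repeats: int = 1) -> CopyNumberCall:
    """Apply the CI-containment rule over the integer universe {1..max_cn}.

    Exactly one integer inside [ci_low, ci_high] -> ``called``; none ->
    ``no_integer``; two or more -> ``ambiguous``.  Deterministic and
    total: every valid (cn_hat, ci) maps to exactly one status.
    """
    lo, hi = ci
    if not lo <= hi:
        raise ValueError(f"inverted interval ({lo}, {hi})")
    inside = [m for m in range(1, max_cn + 1) if lo <= m <= hi]
    if len(inside) == 1:
        status, call = STATUS_CALLED, inside[0]
    elif not inside:
        status, call = STATUS_NO_INTEGER, None
    else:
        status, call = STATUS_AMBIGUOUS, None
    return CopyNumberCall(sample_id=sample_id, assay_id=assay_id, cn_hat=cn_hat,
                          ci_low=lo, ci_high=hi, integer_call=call,
                          status=status, n_repeats=n_repeats)


def resolve_sample(calls: Sequence[CopyNumberCall]) -> CopyNumberCall:
    """Collapse repeated measurement attempts of one sample into one call.

    Called attempts dominate: if at least one attempt called an integer
    and all called attempts agree, the sample resolves to that integer.
    Discordant called attempts, or two or more attempts none of which
    called, mean the sample never resolved and is excluded.  A single
    non-called attempt is returned unchanged (it awaits a repeat).
    """
    calls = list(calls)
    if not calls:
        raise ValueError("resolve_sample requires at least one attempt")
    samples = {c.sample_id for c in calls}
    assays = {c.assay_id for c in calls}
    if len(samples) > 1 or len(assays) > 1:
        raise ValueError("attempts span multiple samples or assays")

    called = [c for c in calls if c.status == STATUS_CALLED]
    if called:
        integers = {c.integer_call for c in called}
        if len(integers) == 1:
            return replace(called[0], n_repeats=len(calls))
        first = called[0]
        return CopyNumberCall(sample_id=first.sample_id, assay_id=first.assay_id,
                              cn_hat=first.cn_hat, ci_low=first.ci_low,
                              ci_high=first.ci_high, integer_call=None,
                              status=STATUS_EXCLUDED, n_repeats=len(calls))
    if len(calls) >= 2:
        first = calls[0]
        return CopyNumberCall(sample_id=first.sample_id, assay_id=first.assay_id,
                              cn_hat=first.cn_hat, ci_low=first.ci_low,
                              ci_high=first.ci_high, integer_call=None,
                              status=STATUS_EXCLUDED, n_repeats=len(calls))
    return calls[0]


def exclusion_rate(n_excluded: int, n_total: int) -> float:
    """Percentage of samples excluded, rounded to one decimal for reporting."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_excluded <= n_total:
        raise ValueError("need 0 <= n_excluded <= n_total")
    return round(100.0 * n_excluded / n_total, 1)


# ---------------------------------------------------------------------------
# Pipeline helpers: wells -> per-sample resolved calls
# ---------------------------------------------------------------------------

def _attempt_from_wells(wells: Sequence[DropletWell], *, max_cn: int,
                        confidence: float) -> CopyNumberCall:
    sample_id, assay_id = wells[0].sample_id, wells[0].assay_id
    nan_call = dict(sample_id=sample_id, assay_id=assay_id, cn_hat=math.nan,
                    ci_low=math.nan, ci_high=math.nan, integer_call=None)
    n = sum(w.n_droplets for w in wells)
    k_ref = sum(w.k_reference for w in wells)
    k_tgt = sum(w.k_target for w in wells)
    if k_ref == n:  # saturated reference: unusable as a normaliser
        return CopyNumberCall(status=STATUS_FAILED, **nan_call)
    if k_tgt == n:
        return CopyNumberCall(status=STATUS_SATURATED, **nan_call)
    target, reference = merge_replicates(wells, confidence=confidence)
    try:
        cn, ci = cn_ratio(target, reference, confidence=confidence)
    except ReferenceFailureError:
        return CopyNumberCall(status=STATUS_FAILED, **nan_call)
    return call_integer(cn, ci, sample_id=sample_id, assay_id=assay_id, max_cn=max_cn)


def call_wells(wells: Iterable[DropletWell], *, max_cn: int = DEFAULT_MAX_CN,
               confidence: float = 0.95) -> list[CopyNumberCall]:
    """Resolve every sample+assay in a well table to a single call.

    Wells sharing a replicate index form one measurement attempt (pooled
    at the droplet level); attempts are then collapsed per sample with
    :func:`resolve_sample`.
    """
    grouped: dict[tuple[str, str], dict[int, list[DropletWell]]] = {}
    for w in wells:
        grouped.setdefault((w.sample_id, w.assay_id), {}).setdefault(w.replicate, []).append(w)

    calls = []
    for (sample_id, assay_id), reps in sorted(grouped.items()):
        attempts = [
            _attempt_from_wells(reps[r], max_cn=max_cn, confidence=confidence)
            for r in sorted(reps)
        ]
        calls.append(resolve_sample(attempts))
    return calls


def call_estimates_frame(estimates: pd.DataFrame, *, max_cn: int = DEFAULT_MAX_CN,
                         confidence: float = 0.95) -> list[CopyNumberCall]:
    """Call copy number from a per-replicate, per-channel estimates table.

    Expects the TSV dialect written by ``quantification.quantify_wells``
    (one row per sample x assay x replicate x channel).
    """
    calls = []
    for (sample_id, assay_id), sample_df in estimates.groupby(
            ["sample_id", "assay_id"], sort=True):
        attempts = []
        for rep, rep_df in sample_df.groupby("replicate", sort=True):
            chans = {r["channel"]: r for _, r in rep_df.iterrows()}
            if TARGET not in chans or REFERENCE not in chans:
                raise ValueError(
                    f"sample {sample_id} assay {assay_id} replicate {rep}: "
                    "need both target and reference rows")
            nan_call = dict(sample_id=str(sample_id), assay_id=str(assay_id),
                            cn_hat=math.nan, ci_low=math.nan, ci_high=math.nan,
                            integer_call=None)
            if chans[TARGET]["status"] == "saturated":
                attempts.append(CopyNumberCall(status=STATUS_SATURATED, **nan_call))
                continue
            if chans[REFERENCE]["status"] == "saturated":
                attempts.append(CopyNumberCall(status=STATUS_FAILED, **nan_call))
                continue
            ests = {
                ch: ConcentrationEstimate(
                    lambda_hat=float(row["lambda"]), ci_low=float(row["ci_low"]),
                    ci_high=float(row["ci_high"]), k=int(row["k"]), n=int(row["n"]),
                    wells_pooled=int(row["wells_pooled"]))
                for ch, row in chans.items()
            }
            try:
                cn, ci = cn_ratio(ests[TARGET], ests[REFERENCE], confidence=confidence)
            except ReferenceFailureError:
                attempts.append(CopyNumberCall(status=STATUS_FAILED, **nan_call))
                continue
            attempts.append(call_integer(cn, ci, sample_id=str(sample_id),
                                         assay_id=str(assay_id), max_cn=max_cn))
        calls.append(resolve_sample(attempts))
    return calls


def calls_to_frame(calls: Iterable[CopyNumberCall]) -> pd.DataFrame:
    rows = [
        dict(sample_id=c.sample_id, assay_id=c.assay_id, cn_hat=c.cn_hat,
             ci_low=c.ci_low, ci_high=c.ci_high,
             call="" if c.integer_call is None else c.integer_call,
             status=c.status, n_repeats=c.n_repeats)
        for c in calls
    ]
    return pd.DataFrame(rows, columns=CALL_TSV_COLUMNS)


def calls_to_tsv(calls: Iterable[CopyNumberCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def calls_from_tsv(path: str | Path) -> list[CopyNumberCall]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "assay_id": str})
    calls = []
    for r in df.itertuples(index=False):
        call = None if pd.isna(r.call) or r.call == "" else int(r.call)
        calls.append(CopyNumberCall(
            sample_id=r.sample_id, assay_id=r.assay_id, cn_hat=float(r.cn_hat),
            ci_low=float(r.ci_low), ci_high=float(r.ci_high), integer_call=call,
            status=r.status, n_repeats=int(r.n_repeats)))
    return calls
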