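"""Subject-level behavioral measures: integration-method TSRT, condition RT
summaries, inhibition proportion, Vincentized RT distributions and
race-model consistency checks.

The central quantity is the target-step reaction time (TSRT), the latency
of the covert STOP process, estimated with the integration method: sort
the no-step RTs, select the RT at the quantile equal to the proportion of
noncompensated redirect trials, and subtract the mean target-step delay.
Combined with a one-up/one-down tracking procedure this is the least
biased of the classical SSRT/TSRT estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class EstimationError(ValueError):
    """Raised when a behavioral estimate is undefined for the given data."""


def integration_tsrt(no_step_rts: Sequence[float], p_noncompensated: float,
                     mean_tsd_ms: float, rank_method: str = "nearest") -> float:
    """Integration-method TSRT estimate, in ms.

    ``rank_method='nearest'`` uses the 1-based nearest-rank quantile
    ``ceil(p * n)`` on the sorted no-step RTs; ``'linear'`` interpolates
    between order statistics.  Translation-equivariant: shifting every
    no-step RT by c shifts the estimate by c; increasing the mean TSD by c
    decreases it by c.
    """
    rts = np.sort(np.asarray(no_step_rts, dtype=float))
    if rts.size == 0:
        raise EstimationError("no-step RT list is empty")
    if not 0.0 < p_noncompensated <= 1.0:
        raise EstimationError(
            f"TSRT undefined for p_noncompensated={p_noncompensated}")
    if rank_method == "nearest":
        rank = math.ceil(p_noncompensated * rts.size)
        quantile_rt = rts[rank - 1]
    elif rank_method == "linear":
        quantile_rt = float(np.quantile(rts, p_noncompensated))
    else:
        raise ValueError(f"unknown rank method {rank_method!r}")
    return float(quantile_rt - mean_tsd_ms)


@dataclass
class VincentizedDistribution:
    """Group RT distribution built from per-subject quantile-bin means."""

    n_bins: int
    subject_bin_means: np.ndarray  # (n_subjects, n_bins)
    group_means: np.ndarray
    group_sem: np.ndarray
    n_dropped: int = 0


def _bin_sizes(n: int, n_bins: int) -> list[int]:
    # equal-count bins; remainder trials go to the earliest bins
    q, r = divmod(n, n_bins)
    return [q + 1] * r + [q] * (n_bins - r)


def vincentize(rts_per_subject: Sequence[Sequence[float]],
               n_bins: int = 10) -> VincentizedDistribution:
    """Vincentized RT distribution: decile means averaged across subjects.

    Each subject's RTs are sorted and split into ``n_bins`` equal-count
    bins (deciles by default); bin means are averaged across subjects with
    the standard error of that across-subject mean.  Subjects with fewer
    than ``n_bins`` RTs cannot fill every bin and are dropped (counted in
    ``n_dropped``).
    """
    per_subject = []
    dropped = 0
    for rts in rts_per_subject:
        rts = np.sort(np.asarray(rts, dtype=float))
        if rts.size < n_bins:
            dropped += 1
            continue
        means, k = [], 0
        for size in _bin_sizes(rts.size, n_bins):
            means.append(rts[k:k + size].mean())
            k += size
        per_subject.append(means)
    if not per_subject:
        raise EstimationError("no subject has enough RTs to Vincentize")
    arr = np.asarray(per_subject)
    sem = (arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
           if arr.shape[0] > 1 else np.zeros(n_bins))
    return VincentizedDistribution(
        n_bins=n_bins, subject_bin_means=arr,
        group_means=arr.mean(axis=0), group_sem=sem, n_dropped=dropped)


@dataclass
class SubjectSummary:
    """Per-subject condition RTs and race-model quantities."""

    subject: int
    no_step_rts: np.ndarray
    compensated_rts: np.ndarray
    noncompensated_rts: np.ndarray
    p_noncompensated: float
    mean_tsd_ms: float
    tsrt_ms: float
    n_excluded: int
    n_indeterminate: int

    def mean_rt(self, condition: str) -> float:
        arr = {
            "no_step": self.no_step_rts,
            "compensated": self.compensated_rts,
            "noncompensated": self.noncompensated_rts,
        }[condition]
        return float(np.mean(arr)) if arr.size else float("nan")


def summarize_subject(df: pd.DataFrame, rank_method: str = "nearest",
                      p_denominator: str = "determinate") -> SubjectSummary:
    """Build a SubjectSummary from a classified, RT-extracted trial table.

    ``df`` needs columns trial_type, outcome, rt_ms, tsd_ms and (optional)
    excluded.  Excluded (anticipation) trials leave the RT pools;
    indeterminate redirect trials leave the inhibition-proportion
    denominator when ``p_denominator='determinate'`` (the default,
    mirroring the online no-change rule) and stay in it with ``'all'``.
    """
    if "excluded" not in df.columns:
        df = df.assign(excluded=False)
    redirect = df[df["trial_type"] == "redirect"]
    if redirect.empty:
        raise EstimationError("dataset has no redirect trials; TSRT undefined")

    kept = df[~df["excluded"].astype(bool)]
    pools = {}
    for condition, outcome in (("no_step", "no_step_saccade"),
                               ("compensated", "compensated"),
                               ("noncompensated", "noncompensated")):
        vals = kept.loc[kept["outcome"] == outcome, "rt_ms"].dropna()
        pools[condition] = vals.to_numpy(dtype=float)

    n_noncomp = int((redirect["outcome"] == "noncompensated").sum())
    n_comp = int((redirect["outcome"] == "compensated").sum())
    n_indet = int(len(redirect) - n_noncomp - n_comp)
    denom = (n_noncomp + n_comp) if p_denominator == "determinate" else len(redirect)
    if denom == 0:
        raise EstimationError("no determinate redirect trials")
    p_noncomp = n_noncomp / denom
    mean_tsd = float(redirect["tsd_ms"].mean())

    tsrt = integration_tsrt(pools["no_step"], p_noncomp, mean_tsd,
                            rank_method=rank_method)
    subject = int(df["subject"].iloc[0]) if "subject" in df.columns else 0
    return SubjectSummary(
        subject=subject,
        no_step_rts=pools["no_step"],
        compensated_rts=pools["compensated"],
        noncompensated_rts=pools["noncompensated"],
        p_noncompensated=p_noncomp,
        mean_tsd_ms=mean_tsd,
        tsrt_ms=tsrt,
        n_excluded=int(df["excluded"].astype(bool).sum()),
        n_indeterminate=n_indet,
    )


def race_consistency_report(summary: SubjectSummary,
                            p_range: tuple[float, float] = (0.40, 0.60)) -> dict:
    """Diagnostic checks that the data behave as the race model predicts.

    Because the race censors slow GO finishes, noncompensated RTs should
    be faster on average than no-step RTs; the tracking procedure should
    hold the noncompensated proportion near one half; and the STOP-latency
    estimate should be positive.
    """
    noncomp_mean = summary.mean_rt("noncompensated")
    no_step_mean = summary.mean_rt("no_step")
    checks = {
        "noncompensated_faster_than_no_step": {
            "passed": bool(noncomp_mean <= no_step_mean),
            "margin_ms": float(no_step_mean - noncomp_mean),
        },
        "p_noncompensated_near_half": {
            "passed": bool(p_range[0] <= summary.p_noncompensated <= p_range[1]),
            "value": float(summary.p_noncompensated),
            "range": list(p_range),
        },
        "tsrt_positive": {
            "passed": bool(summary.tsrt_ms > 0),
            "value": float(summary.tsrt_ms),
        },
    }
    checks["all_passed"] = all(
        c["passed"] for c in checks.values() if isinstance(c, dict))
    return checks


def summaries_to_frame(summaries: Sequence[SubjectSummary],
                       group_labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Tabulate subject summaries (one row per subject) for group statistics."""
    rows = []
    for i, s in enumerate(summaries):
        rows.append({
            "subject": s.subject,
            "group": group_labels[i] if group_labels is not None else "all",
            "no_step_rt_ms": s.mean_rt("no_step"),
            "compensated_rt_ms": s.mean_rt("compensated"),
            "noncompensated_rt_ms": s.mean_rt("noncompensated"),
            "tsrt_ms": s.tsrt_ms,
            "p_noncompensated": s.p_noncompensated,
            "mean_tsd_ms": s.mean_tsd_ms,
            "n_excluded": s.n_excluded,
        })
    return pd.DataFrame(rows)
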