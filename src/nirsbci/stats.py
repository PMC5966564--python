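"""Offline statistics: ROI averaging, peak responses, group summaries and tests.

These are the analyses run after a session (or across subjects): spatial
averaging of optodes into prefrontal regions of interest, the trial-locked
peak-response statistic on MACD-filtered signals, mean/sd summaries,
Cohen's d, two-sample t-tests, and the exact-binomial chance-level
threshold used to judge whether a per-subject classification accuracy
exceeds chance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .hemodynamics import HemoStream
from .protocol import TrialSpec

__all__ = [
    "ROIMap",
    "PeakResponse",
    "GroupSummary",
    "roi_average",
    "peak_response",
    "group_summary",
    "cohens_d",
    "unpaired_t_test",
    "binomial_chance_threshold",
]


@dataclass(frozen=True)
class ROIMap:
    """Disjoint optode groups covering the montage, keyed by ROI id (1-4).

    Optode indices are 1-based.  The 16-optode headband maps four contiguous
    groups of four; the 4-optode headband is the identity map (each optode
    is its own region).
    """

    rois: dict[int, tuple[int, ...]]

    def __post_init__(self) -> None:
        all_opt = [o for members in self.rois.values() for o in members]
        if len(all_opt) != len(set(all_opt)):
            raise ValueError("ROI optode sets must be disjoint")

    @property
    def n_optodes(self) -> int:
        return sum(len(m) for m in self.rois.values())

    @classmethod
    def for_profile(cls, n_optodes: int) -> "ROIMap":
        if n_optodes % 4 == 0 and n_optodes >= 8:
            group = n_optodes // 4
            return cls(
                {r + 1: tuple(range(r * group + 1, (r + 1) * group + 1)) for r in range(4)}
            )
        return cls({k: (k,) for k in range(1, n_optodes + 1)})


@dataclass(frozen=True)
class PeakResponse:
    """Peak statistic for one (trial, ROI, chromophore)."""

    trial_index: int
    roi_id: int
    chromophore: str
    value: float


@dataclass(frozen=True)
class GroupSummary:
    """Sample mean and sd (n-1 denominator) of a set of values."""

    n: int
    mean: float
    sd: float


def roi_average(stream: HemoStream, roi_map: ROIMap) -> HemoStream:
    """Unweighted mean over each ROI's optodes, per chromophore and sample.

    Returns a stream whose optode axis is the sorted ROI ids.
    """
    covered = sorted(o for members in roi_map.rois.values() for o in members)
    if covered != list(range(1, stream.n_optodes + 1)):
        missing = set(range(1, stream.n_optodes + 1)) - set(covered)
        raise ValueError(f"ROI map does not cover optodes {sorted(missing)}")
    roi_ids = sorted(roi_map.rois)
    hbo = np.stack(
        [stream.hbo[:, [o - 1 for o in roi_map.rois[r]]].mean(axis=1) for r in roi_ids],
        axis=1,
    )
    hhb = np.stack(
        [stream.hhb[:, [o - 1 for o in roi_map.rois[r]]].mean(axis=1) for r in roi_ids],
        axis=1,
    )
    return HemoStream(time=stream.time, hbo=hbo, hhb=hhb)


def peak_response(
    time: np.ndarray, signal: np.ndarray, trial: TrialSpec, pre_window_s: float = 2.0
) -> float:
    """Trial peak: max within the 30 s post-onset window minus the pre-onset mean.

    The pre-onset reference is the mean over ``[onset - 2 s, onset)``; the
    peak is taken over the half-open window ``[onset, onset + 30 s)``.
    """
    time = np.asarray(time, float)
    signal = np.asarray(signal, float)
    pre = (time >= trial.onset - pre_window_s) & (time < trial.onset)
    post = (time >= trial.onset) & (time < trial.onset + trial.trial_window_s)
    if not np.any(pre):
        raise ValueError(f"trial {trial.index}: no samples in the pre-onset window")
    if not np.any(post):
        raise ValueError(f"trial {trial.index}: no samples in the trial window")
    return float(signal[post].max() - signal[pre].mean())


def group_summary(values) -> GroupSummary:
    """Mean and sample standard deviation; sd is NaN for a single value."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else float("nan")
    return GroupSummary(n=int(arr.size), mean=float(arr.mean()), sd=sd)


def cohens_d(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Cohen's d from group summaries, pooled sd with (n-1) weights.

    Returns the unsigned effect size |mean2 - mean1| / s_pooled.  A zero
    pooled sd with unequal means is flagged as an infinite effect.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations cannot be negative")
    pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    diff = abs(mean2 - mean1)
    if pooled == 0:
        if diff == 0:
            return 0.0
        warnings.warn("zero pooled sd with unequal means: infinite effect size")
        return float("inf")
    return float(diff / pooled)


def unpaired_t_test(
    values1, values2, equal_var: bool = True
) -> tuple[float, float, float]:
    """Two-tailed two-sample t-test: returns (t, df, p).

    Equal-variance (classic) by default; Welch via ``equal_var=False``.
    """
    a = np.asarray(list(values1), dtype=float)
    b = np.asarray(list(values2), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            # identical degenerate groups: no evidence against equality
            df = a.size + b.size - 2
            return 0.0, float(df), 1.0
        raise ValueError("both groups have zero variance; t statistic undefined")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def binomial_chance_threshold(
    n_trials: int, p_chance: float = 0.5, alpha: float = 0.05
) -> float:
    """Minimal accuracy (%) significantly above chance by the exact binomial test.

    The smallest k/n such that P(X >= k | n, p_chance) <= alpha under the
    binomial null; e.g. 15/20 = 75 % for a 20-trial session at alpha = 0.05,
    and 9/10 = 90 % for a 10-trial testing phase.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0 < alpha:
        raise ValueError("alpha must be positive")
    if alpha >= 1:
        return 0.0
    for k in range(n_trials + 1):
        # sf(k-1) = P(X >= k)
        if sps.binom.sf(k - 1, n_trials, p_chance) <= alpha:
            return 100.0 * k / n_trials
    return float("nan")  # alpha smaller than p^n: no attainable threshold
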