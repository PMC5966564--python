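"""Trial sequencing, session timeline and stream segmentation.

A session is a 10 s rest baseline followed by 20 auditory readback trials,
each occupying a 30 s analysis window anchored at message onset.  Working
memory load alternates pseudo-randomly between *low* and *high* under two
constraints: the first half of the session (the labeled training block)
contains exactly half of each load, and the same load never occurs on more
than two successive trials.  Trials 1-10 form phase A (data gathering),
trials 11-20 phase C (online testing); the classifier is trained in between
(phase B).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hemodynamics import DeviceProfile, HemoStream

__all__ = [
    "LOADS",
    "TrialSpec",
    "TimingConfig",
    "SessionProtocol",
    "TrialTensor",
    "generate_trial_sequence",
    "build_timeline",
    "segment_trial",
]

LOADS = ("low", "high")


@dataclass(frozen=True)
class TrialSpec:
    """One readback trial: 1-based index, load label and onset in seconds."""

    index: int
    load: str
    onset: float
    trial_window_s: float = 30.0
    response_window_s: float = 18.0

    def __post_init__(self) -> None:
        if self.load not in LOADS:
            raise ValueError(f"load must be one of {LOADS}, got {self.load!r}")
        if self.trial_window_s <= 0 or self.response_window_s <= 0:
            raise ValueError("trial windows must be positive")

    @property
    def end(self) -> float:
        return self.onset + self.trial_window_s


@dataclass(frozen=True)
class TimingConfig:
    """Session timing constants (seconds)."""

    baseline_s: float = 10.0
    trial_window_s: float = 30.0
    response_window_s: float = 18.0
    inter_trial_gap_s: float = 5.0

    def __post_init__(self) -> None:
        if min(self.baseline_s, self.trial_window_s, self.response_window_s) <= 0:
            raise ValueError("durations must be positive")
        if self.inter_trial_gap_s < 0:
            raise ValueError("inter-trial gap cannot be negative")


@dataclass
class SessionProtocol:
    """Ordered trial list plus the session timing that produced it."""

    trials: list[TrialSpec]
    timing: TimingConfig = field(default_factory=TimingConfig)

    def __post_init__(self) -> None:
        onsets = [t.onset for t in self.trials]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("trial onsets must be strictly increasing")
        if self.trials and self.trials[0].onset < self.timing.baseline_s:
            raise ValueError("first trial starts before the baseline ends")
        for a, b in zip(self.trials, self.trials[1:]):
            if b.onset < a.end:
                raise ValueError(
                    f"trial {b.index} overlaps the window of trial {a.index}"
                )

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def phase_a(self) -> list[TrialSpec]:
        """First half: labeled data-gathering trials."""
        return self.trials[: len(self.trials) // 2]

    @property
    def phase_c(self) -> list[TrialSpec]:
        """Second half: online testing trials."""
        return self.trials[len(self.trials) // 2 :]

    @property
    def duration(self) -> float:
        """Seconds from session start to the end of the last trial window."""
        if not self.trials:
            return self.timing.baseline_s
        return self.trials[-1].end + self.timing.inter_trial_gap_s


@dataclass
class TrialTensor:
    """Filtered signal for one trial: array (optode, chromophore, sample).

    Chromophore axis is (HbO2, hHb).  Sample count is ``round(30 * fs)``.
    """

    values: np.ndarray
    load: str
    index: int
    onset: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1] != 2:
            raise ValueError("tensor must have shape (optode, 2, sample)")


def generate_trial_sequence(
    n_per_class: int,
    first_block_balanced: bool = True,
    max_run: int = 2,
    seed: int | np.random.Generator = 0,
    max_tries: int = 200_000,
) -> list[str]:
    """Draw a load sequence uniformly from the constrained sequence space.

    Constraints: the sequence holds ``n_per_class`` of each load; if
    ``first_block_balanced``, the first half holds exactly half of each; no
    load repeats on more than ``max_run`` successive trials.  Uniformity over
    the valid set is obtained by rejection sampling from uniform shuffles of
    the label multiset, which is exact and cheap because the valid fraction
    is large for the session sizes used here.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if max_run < 1:
        raise ValueError("max_run must be >= 1")
    if first_block_balanced and n_per_class % 2:
        raise ValueError(
            "first-block balance needs an even number of trials per class"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.array([0] * n_per_class + [1] * n_per_class)
    half = n_per_class  # first half of a 2*n_per_class sequence
    for _ in range(max_tries):
        rng.shuffle(labels)
        if first_block_balanced and labels[:half].sum() * 2 != half:
            continue
        runs = np.diff(np.flatnonzero(np.concatenate(([1], np.diff(labels), [1]))))
        if runs.max() > max_run:
            continue
        return [LOADS[v] for v in labels]
    raise ValueError(
        "could not draw a sequence satisfying the constraints "
        f"(n_per_class={n_per_class}, max_run={max_run})"
    )


def build_timeline(
    sequence: list[str], timing: TimingConfig | None = None
) -> SessionProtocol:
    """Lay the load sequence onto the session clock.

    Trial k (1-based) starts at ``baseline + (k-1) * (window + gap)`` so the
    baseline precedes trial 1 and the 30 s windows never overlap.
    """
    timing = timing or TimingConfig()
    period = timing.trial_window_s + timing.inter_trial_gap_s
    trials = [
        TrialSpec(
            index=k + 1,
            load=load,
            onset=timing.baseline_s + k * period,
            trial_window_s=timing.trial_window_s,
            response_window_s=timing.response_window_s,
        )
        for k, load in enumerate(sequence)
    ]
    return SessionProtocol(trials=trials, timing=timing)


def segment_trial(
    filtered: HemoStream, trial: TrialSpec, profile: DeviceProfile
) -> TrialTensor:
    """Extract the half-open window [onset, onset + 30 s) as a trial tensor.

    The tensor has shape (n_optodes, 2, round(30 * fs)); an incomplete
    window raises, naming the trial, so that online consumers only ever see
    fully covered trials.
    """
    if filtered.n_optodes != profile.n_optodes:
        raise ValueError(
            f"stream has {filtered.n_optodes} optodes, profile expects {profile.n_optodes}"
        )
    n_expected = round(trial.trial_window_s * profile.sampling_rate)
    mask = (filtered.time >= trial.onset) & (filtered.time < trial.onset + trial.trial_window_s)
    n_found = int(mask.sum())
    if n_found != n_expected:
        raise ValueError(
            f"trial {trial.index}: stream covers {n_found} of "
            f"{n_expected} samples in [{trial.onset}, {trial.end})"
        )
    # (sample, optode) -> (optode, chromophore, sample)
    values = np.stack([filtered.hbo[mask].T, filtered.hhb[mask].T], axis=1)
    return TrialTensor(values=values, load=trial.load, index=trial.index, onset=trial.onset)
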