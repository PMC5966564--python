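"""Whole-session configuration: one validated YAML binding every stage.

A session config collects the device profile, protocol timing, filter
windows, classifier settings and synthetic-generator parameters under one
schema with explicit seeds.  Unknown keys are rejected at every level so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .hemodynamics import DeviceProfile
from .macd import MacdConfig
from .protocol import TimingConfig
from .synthetic import HrfParams, NoiseParams, SyntheticConfig

__all__ = ["SessionConfig", "load_session_config"]


class ConfigError(ValueError):
    """A session config violated the documented schema."""


@dataclass
class SessionConfig:
    """Validated settings for one session run, with all seeds explicit."""

    profile: DeviceProfile
    timing: TimingConfig
    macd: MacdConfig
    synthetic: SyntheticConfig
    c_grid: np.ndarray
    seed: int
    cv_seed: int

    def provenance(self) -> dict:
        """Flat, serializable view for session reports."""
        return {
            "n_optodes": self.profile.n_optodes,
            "fs_hz": self.profile.sampling_rate,
            "short_window_s": self.macd.short_window_s,
            "long_window_s": self.macd.long_window_s,
            "baseline_s": self.timing.baseline_s,
            "trial_window_s": self.timing.trial_window_s,
            "inter_trial_gap_s": self.timing.inter_trial_gap_s,
            "c_grid": [float(c) for c in self.c_grid],
            "seed": self.seed,
            "cv_seed": self.cv_seed,
        }


_SECTIONS = {"profile", "timing", "filter", "classifier", "synthetic", "seed"}
_TIMING_KEYS = {"baseline_s", "trial_window_s", "response_window_s", "inter_trial_gap_s"}
_FILTER_KEYS = {"short_window_s", "long_window_s", "init_to_first_sample"}
_CLASSIFIER_KEYS = {"c_grid", "cv_seed"}
_SYNTH_KEYS = {
    "amp_low", "amp_high", "hhb_ratio", "time_to_peak_s", "dispersion",
    "onset_delay_s", "white_sd", "cardiac_amp", "cardiac_freq", "resp_amp",
    "resp_freq", "mayer_amp", "mayer_freq", "drift_amp", "hhb_scale",
    "spatial_map", "seed",
}
_PROFILE_KEYS = {"n_optodes", "fs_hz", "wavelengths_nm", "separation_mm", "dpf", "extinction_coeffs"}


def _reject_unknown(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")


def load_session_config(path: str | Path) -> SessionConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: session config must be a mapping")
    _reject_unknown(raw, _SECTIONS, str(path))
    if "seed" not in raw:
        raise ConfigError(f"{path}: a top-level seed is required")
    seed = int(raw["seed"])

    prof = raw.get("profile", {})
    _reject_unknown(prof, _PROFILE_KEYS, f"{path}:profile")
    kwargs: dict = {}
    if "extinction_coeffs" in prof:
        kwargs["extinction"] = {
            float(wl): tuple(map(float, pair))
            for wl, pair in prof["extinction_coeffs"].items()
        }
    profile = DeviceProfile(
        n_optodes=int(prof.get("n_optodes", 16)),
        sampling_rate=float(prof.get("fs_hz", 2.0)),
        wavelengths=tuple(float(w) for w in prof.get("wavelengths_nm", (730, 850))),
        separation_mm=float(prof.get("separation_mm", 25.0)),
        dpf=float(prof.get("dpf", 5.97)),
        **kwargs,
    )

    tim = raw.get("timing", {})
    _reject_unknown(tim, _TIMING_KEYS, f"{path}:timing")
    timing = TimingConfig(**{k: float(v) for k, v in tim.items()})

    filt = raw.get("filter", {})
    _reject_unknown(filt, _FILTER_KEYS, f"{path}:filter")
    macd = MacdConfig(
        short_window_s=float(filt.get("short_window_s", 6.0)),
        long_window_s=float(filt.get("long_window_s", 13.0)),
        sampling_rate=profile.sampling_rate,
        init_to_first_sample=bool(filt.get("init_to_first_sample", True)),
    )

    clf = raw.get("classifier", {})
    _reject_unknown(clf, _CLASSIFIER_KEYS, f"{path}:classifier")
    c_grid = np.asarray(clf.get("c_grid", 10.0 ** np.arange(-3, 5)), dtype=float)
    cv_seed = int(clf.get("cv_seed", seed))

    syn = dict(raw.get("synthetic", {}))
    _reject_unknown(syn, _SYNTH_KEYS, f"{path}:synthetic")
    hrf = HrfParams(
        onset_delay_s=float(syn.get("onset_delay_s", 0.0)),
        time_to_peak_s=float(syn.get("time_to_peak_s", 6.0)),
        dispersion=float(syn.get("dispersion", 6.0)),
    )
    noise_defaults = NoiseParams()
    noise = NoiseParams(
        **{
            k: float(syn.get(k, getattr(noise_defaults, k)))
            for k in (
                "white_sd", "cardiac_amp", "cardiac_freq", "resp_amp",
                "resp_freq", "mayer_amp", "mayer_freq", "drift_amp", "hhb_scale",
            )
        }
    )
    spatial = syn.get("spatial_map")
    synthetic = SyntheticConfig(
        profile=profile,
        hrf=hrf,
        amp_low=float(syn.get("amp_low", 0.05)),
        amp_high=float(syn.get("amp_high", 0.2)),
        hhb_ratio=float(syn.get("hhb_ratio", -1.0 / 3.0)),
        noise=noise,
        spatial_map=None if spatial is None else np.asarray(spatial, dtype=float),
        seed=int(syn.get("seed", seed)),
    )

    return SessionConfig(
        profile=profile, timing=timing, macd=macd, synthetic=synthetic,
        c_grid=c_grid, seed=seed, cv_seed=cv_seed,
    )
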