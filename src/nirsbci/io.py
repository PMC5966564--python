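"""File formats, configuration loading, stream replay and session reports.

Streams travel as long-format CSV: one row per (timestamp, optode,
channel).  Concentration streams use columns ``time_s, optode, chromophore,
value_umol_l`` with chromophore in {hbo, hhb}; raw optical streams use
``time_s, optode, wavelength_nm, intensity``.  Trial events are
``trial_index, onset_s, load``.  Device profiles and session settings load
from YAML with strict (unknown-key-rejecting) validation, and a finished
session serializes to a round-trippable JSON report.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
import time as _time

import numpy as np
import pandas as pd
import yaml

from .classifier import PredictionRecord, SessionMetrics, WMClassifier
from .hemodynamics import DeviceProfile, HemoStream, OpticalStream
from .protocol import LOADS, SessionProtocol, TimingConfig, TrialSpec

__all__ = [
    "read_hemo_csv",
    "write_hemo_csv",
    "read_optical_csv",
    "write_optical_csv",
    "read_events_csv",
    "write_events_csv",
    "load_profile",
    "stream_player",
    "SessionReport",
]

_PROFILE_KEYS = {"n_optodes", "fs_hz", "wavelengths_nm", "separation_mm", "dpf", "extinction_coeffs"}


class SchemaError(ValueError):
    """A file or config violated its documented schema."""


def load_profile(path: str | Path) -> DeviceProfile:
    """Read a device profile from YAML, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: profile must be a mapping")
    unknown = set(raw) - _PROFILE_KEYS
    if unknown:
        raise SchemaError(f"{path}: unknown profile keys {sorted(unknown)}")
    kwargs: dict = {}
    if "extinction_coeffs" in raw:
        kwargs["extinction"] = {
            float(wl): tuple(map(float, pair)) for wl, pair in raw["extinction_coeffs"].items()
        }
    return DeviceProfile(
        n_optodes=int(raw["n_optodes"]),
        sampling_rate=float(raw["fs_hz"]),
        wavelengths=tuple(float(w) for w in raw.get("wavelengths_nm", (730, 850))),
        separation_mm=float(raw.get("separation_mm", 25.0)),
        dpf=float(raw.get("dpf", 5.97)),
        **kwargs,
    )


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def write_hemo_csv(stream: HemoStream, path: str | Path) -> None:
    n, n_opt = stream.hbo.shape
    optode = np.tile(np.repeat(np.arange(1, n_opt + 1), 2), n)
    chrom = np.tile(["hbo", "hhb"], n * n_opt)
    time_col = np.repeat(stream.time, 2 * n_opt)
    values = np.stack([stream.hbo, stream.hhb], axis=2).reshape(-1)
    pd.DataFrame(
        {"time_s": time_col, "optode": optode, "chromophore": chrom, "value_umol_l": values}
    ).to_csv(path, index=False, float_format="%.17g")


def read_hemo_csv(path: str | Path, profile: DeviceProfile | None = None) -> HemoStream:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, ["time_s", "optode", "chromophore", "value_umol_l"], path)
    bad = ~df["chromophore"].isin(["hbo", "hhb"])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(f"{path}: row {row}: bad chromophore {df['chromophore'].iloc[row]!r}")
    times = np.unique(df["time_s"].to_numpy())
    first = df[df["optode"] == 1]
    order = first[first["chromophore"] == "hbo"]["time_s"].to_numpy()
    if order.size > 1 and not np.all(np.diff(order) > 0):
        raise SchemaError(f"{path}: timestamps are not strictly increasing")
    n_opt = int(df["optode"].max())
    if profile is not None and n_opt != profile.n_optodes:
        raise SchemaError(
            f"{path}: file has {n_opt} optodes but profile expects {profile.n_optodes}"
        )
    hbo = np.empty((times.size, n_opt))
    hhb = np.empty((times.size, n_opt))
    try:
        for name, target in (("hbo", hbo), ("hhb", hhb)):
            sub = df[df["chromophore"] == name]
            piv = sub.pivot(index="time_s", columns="optode", values="value_umol_l")
            piv = piv.reindex(index=times, columns=range(1, n_opt + 1))
            if piv.isna().any().any():
                raise SchemaError(f"{path}: missing {name} samples for some (time, optode)")
            target[:] = piv.to_numpy()
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc
    return HemoStream(time=times, hbo=hbo, hhb=hhb)


def write_optical_csv(stream: OpticalStream, wavelengths: tuple[float, float], path: str | Path) -> None:
    n, n_opt, _ = stream.intensity.shape
    rows = {
        "time_s": np.repeat(stream.time, 2 * n_opt),
        "optode": np.tile(np.repeat(np.arange(1, n_opt + 1), 2), n),
        "wavelength_nm": np.tile(list(wavelengths), n * n_opt),
        "intensity": stream.intensity.reshape(-1),
    }
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_optical_csv(path: str | Path, profile: DeviceProfile) -> OpticalStream:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, ["time_s", "optode", "wavelength_nm", "intensity"], path)
    n_opt = int(df["optode"].max())
    if n_opt != profile.n_optodes:
        raise SchemaError(
            f"{path}: file has {n_opt} optodes but profile expects {profile.n_optodes}"
        )
    times = np.unique(df["time_s"].to_numpy())
    intensity = np.empty((times.size, n_opt, 2))
    for w, wl in enumerate(profile.wavelengths):
        sub = df[df["wavelength_nm"] == wl]
        piv = sub.pivot(index="time_s", columns="optode", values="intensity")
        piv = piv.reindex(index=times, columns=range(1, n_opt + 1))
        if piv.isna().any().any():
            raise SchemaError(f"{path}: missing intensities at {wl} nm")
        intensity[:, :, w] = piv.to_numpy()
    return OpticalStream(time=times, intensity=intensity)


def write_events_csv(protocol: SessionProtocol, path: str | Path) -> None:
    pd.DataFrame(
        {
            "trial_index": [t.index for t in protocol.trials],
            "onset_s": [t.onset for t in protocol.trials],
            "load": [t.load for t in protocol.trials],
        }
    ).to_csv(path, index=False)


def read_events_csv(path: str | Path, timing: TimingConfig | None = None) -> SessionProtocol:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, ["trial_index", "onset_s", "load"], path)
    timing = timing or TimingConfig()
    bad = ~df["load"].isin(LOADS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(f"{path}: row {row}: load must be one of {LOADS}")
    trials = [
        TrialSpec(
            index=int(r.trial_index),
            load=str(r.load),
            onset=float(r.onset_s),
            trial_window_s=timing.trial_window_s,
            response_window_s=timing.response_window_s,
        )
        for r in df.itertuples()
    ]
    return SessionProtocol(trials=trials, timing=timing)


def stream_player(stream: HemoStream, real_time: bool = False):
    """Yield ``(t, hbo_row, hhb_row)`` strictly in time order.

    This is the replay boundary that enforces the causal contract:
    downstream consumers receive one sample at a time and can never observe
    a future sample.  With ``real_time`` the generator sleeps to pace the
    replay at the recorded timestamps; outputs are identical either way.
    """
    t0 = _time.monotonic()
    start = stream.time[0] if stream.time.size else 0.0
    for i in range(stream.time.size):
        if real_time:
            target = stream.time[i] - start
            lag = target - (_time.monotonic() - t0)
            if lag > 0:
                _time.sleep(lag)
        yield float(stream.time[i]), stream.hbo[i].copy(), stream.hhb[i].copy()


@dataclass
class SessionReport:
    """Serializable record of one online session."""

    predictions: list[dict]
    selected_C: float
    cv_accuracy: float
    cv_accuracy_per_C: dict[str, float]
    training_accuracy: float
    metrics: dict
    profile: dict
    seeds: dict
    package_version: str = "0.1.0"
    created_unix: float = field(default_factory=lambda: _time.time())

    @classmethod
    def from_session(
        cls,
        model: WMClassifier,
        records: list[PredictionRecord],
        metrics: SessionMetrics,
        profile: DeviceProfile,
        seeds: dict | None = None,
    ) -> "SessionReport":
        return cls(
            predictions=[asdict(r) for r in records],
            selected_C=model.selected_C,
            cv_accuracy=model.cv_accuracy,
            cv_accuracy_per_C={str(k): v for k, v in model.cv_accuracy_per_C.items()},
            training_accuracy=model.training_accuracy,
            metrics=asdict(metrics),
            profile={
                "n_optodes": profile.n_optodes,
                "fs_hz": profile.sampling_rate,
                "wavelengths_nm": list(profile.wavelengths),
                "separation_mm": profile.separation_mm,
                "dpf": profile.dpf,
            },
            seeds=seeds or {},
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, allow_nan=True))

    @classmethod
    def read(cls, path: str | Path) -> "SessionReport":
        return cls(**json.loads(Path(path).read_text()))
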