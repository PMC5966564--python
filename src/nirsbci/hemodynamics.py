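"""Conversion of raw two-wavelength optical intensities to hemoglobin concentration changes.

Continuous-wave fNIRS devices measure light intensity at two near-infrared
wavelengths (here 730 and 850 nm, on either side of the hemoglobin isosbestic
point).  A drop in detected intensity relative to a rest baseline reflects
increased absorption; the modified Beer-Lambert law (mBLL) maps the
optical-density change at the two wavelengths linearly onto changes in
oxygenated (HbO2) and deoxygenated (hHb) hemoglobin concentration:

    dOD(lambda) = [ eps_HbO2(lambda) * dC_HbO2 + eps_hHb(lambda) * dC_hHb ] * d * DPF

where ``d`` is the source-detector separation (cm) and DPF the differential
pathlength factor.  Inverting the 2x2 extinction system per sample yields
concentration changes in micromol/L relative to the baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_EXTINCTION",
    "DeviceProfile",
    "OpticalStream",
    "BaselineRecord",
    "HemoStream",
    "InvalidFrameError",
    "compute_baseline",
    "od_change",
    "extinction_matrix",
    "mbll_convert",
    "forward_od",
    "check_saturation",
]

# Molar extinction coefficients, 1/(cm * mol/L), from the standard compilation of
# hemoglobin spectra (Prahl / Oregon Medical Laser Center tabulation).  Keyed by
# wavelength in nm; values are (HbO2, hHb).  Overridable per device profile.
DEFAULT_EXTINCTION: dict[float, tuple[float, float]] = {
    730.0: (390.0, 1102.2),
    850.0: (1058.0, 691.32),
}


class InvalidFrameError(ValueError):
    """Raised when an optical frame contains non-positive intensities."""


@dataclass(frozen=True)
class DeviceProfile:
    """Geometry and acquisition parameters of a continuous-wave fNIRS device.

    The two profiles used throughout the package are a 16-optode desktop
    headband sampling at 2 Hz and a 4-optode wireless headband sampling at
    4 Hz, both with 25 mm source-detector separation and DPF 5.97.
    """

    n_optodes: int
    sampling_rate: float
    wavelengths: tuple[float, float] = (730.0, 850.0)
    separation_mm: float = 25.0
    dpf: float = 5.97
    extinction: dict[float, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EXTINCTION)
    )

    def __post_init__(self) -> None:
        if self.n_optodes < 1:
            raise ValueError(f"n_optodes must be >= 1, got {self.n_optodes}")
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.wavelengths[0] == self.wavelengths[1]:
            raise ValueError("the two wavelengths must be distinct")
        if self.separation_mm <= 0:
            raise ValueError("separation must be > 0")
        if self.dpf <= 0:
            raise ValueError("dpf must be > 0")
        for wl in self.wavelengths:
            if wl not in self.extinction:
                raise ValueError(f"no extinction coefficients for {wl} nm")

    @property
    def pathlength_cm(self) -> float:
        """Effective photon pathlength: separation (cm) times DPF."""
        return self.separation_mm / 10.0 * self.dpf

    @classmethod
    def sim16(cls) -> "DeviceProfile":
        """Desktop 16-optode headband, 2 Hz (simulator experiments)."""
        return cls(n_optodes=16, sampling_rate=2.0)

    @classmethod
    def flight4(cls) -> "DeviceProfile":
        """Wireless 4-optode headband, 4 Hz (in-flight experiments)."""
        return cls(n_optodes=4, sampling_rate=4.0)


@dataclass
class OpticalStream:
    """Time-stamped raw intensities, shape ``(n_samples, n_optodes, 2)``.

    The last axis follows the profile's wavelength order (730 then 850 nm by
    default).  Intensities are in arbitrary detector units and must be
    positive for valid frames.
    """

    time: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3 or self.intensity.shape[2] != 2:
            raise ValueError("intensity must have shape (n_samples, n_optodes, 2)")
        if self.time.shape[0] != self.intensity.shape[0]:
            raise ValueError("time and intensity lengths differ")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_optodes(self) -> int:
        return self.intensity.shape[1]


@dataclass
class BaselineRecord:
    """Mean intensity per (optode, wavelength) over the rest window."""

    mean_intensity: np.ndarray  # (n_optodes, 2)
    window_s: float = 10.0
    n_frames: int = 0

    def __post_init__(self) -> None:
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=float)
        if self.n_frames < 1:
            raise ValueError("baseline must be computed over at least one frame")
        if np.any(self.mean_intensity <= 0):
            raise ValueError("baseline means must all be positive")


@dataclass
class HemoStream:
    """Baseline-relative concentration changes in micromol/L.

    ``hbo`` and ``hhb`` have shape ``(n_samples, n_optodes)`` and share the
    ``time`` axis (seconds from session start).
    """

    time: np.ndarray
    hbo: np.ndarray
    hhb: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.hbo = np.atleast_2d(np.asarray(self.hbo, dtype=float))
        self.hhb = np.atleast_2d(np.asarray(self.hhb, dtype=float))
        if self.hbo.shape != self.hhb.shape:
            raise ValueError("hbo and hhb shapes differ")
        if self.time.shape[0] != self.hbo.shape[0]:
            raise ValueError("time and signal lengths differ")
        if not (np.all(np.isfinite(self.hbo)) and np.all(np.isfinite(self.hhb))):
            raise ValueError("concentration values must be finite")

    @property
    def n_optodes(self) -> int:
        return self.hbo.shape[1]


def compute_baseline(stream: OpticalStream, window_s: float = 10.0) -> BaselineRecord:
    """Arithmetic mean of intensities over the initial rest window.

    The baseline rest period precedes all trials; frames with
    ``time < window_s`` contribute.
    """
    mask = stream.time < window_s
    if not np.any(mask):
        raise ValueError("no frames inside the baseline window")
    frames = stream.intensity[mask]
    if np.any(frames <= 0):
        bad = np.argwhere(frames <= 0)
        raise InvalidFrameError(
            f"non-positive intensity in baseline window (optode {bad[0][1] + 1})"
        )
    return BaselineRecord(
        mean_intensity=frames.mean(axis=0), window_s=window_s, n_frames=int(mask.sum())
    )


def od_change(intensity: np.ndarray, baseline: BaselineRecord) -> np.ndarray:
    """Optical-density change ``-log10(I / I0)`` per (optode, wavelength).

    The sign convention makes an intensity *drop* (more absorption) a
    *positive* dOD.  Accepts a single frame ``(n_optodes, 2)`` or a stream
    ``(n_samples, n_optodes, 2)``; the conversion is stateless per frame.
    """
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity <= 0):
        bad = np.argwhere(intensity <= 0)
        optode_axis = 0 if intensity.ndim == 2 else 1
        raise InvalidFrameError(
            f"non-positive intensity at optode {bad[0][optode_axis] + 1}"
        )
    return -np.log10(intensity / baseline.mean_intensity)


def extinction_matrix(profile: DeviceProfile) -> np.ndarray:
    """2x2 matrix E with E[i, j] = eps(chromophore j at wavelength i).

    Rows follow the profile wavelength order; columns are (HbO2, hHb).
    """
    return np.array([profile.extinction[wl] for wl in profile.wavelengths], dtype=float)


def _solve_matrix(profile: DeviceProfile) -> np.ndarray:
    ext = extinction_matrix(profile)
    if np.linalg.cond(ext) > 1e8:
        raise ValueError(
            "extinction matrix is singular or ill-conditioned; "
            "check the configured coefficients"
        )
    return np.linalg.inv(ext)


def mbll_convert(
    dod_730: np.ndarray, dod_850: np.ndarray, profile: DeviceProfile
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the modified Beer-Lambert law: dOD pair -> (dHbO2, dhHb) in uM.

    Linear and stateless per sample: zero input maps to zero output and the
    conversion commutes with stream concatenation.
    """
    inv = _solve_matrix(profile)
    dod = np.stack([np.asarray(dod_730, float), np.asarray(dod_850, float)], axis=-1)
    conc_molar = dod @ inv.T / profile.pathlength_cm
    conc_um = conc_molar * 1e6
    return conc_um[..., 0], conc_um[..., 1]


def forward_od(
    hbo_um: np.ndarray, hhb_um: np.ndarray, profile: DeviceProfile
) -> tuple[np.ndarray, np.ndarray]:
    """Forward Beer-Lambert model: concentrations (uM) -> dOD at each wavelength.

    Exact inverse of :func:`mbll_convert`; used to encode synthetic
    concentration streams as raw intensities and as the round-trip oracle.
    """
    ext = extinction_matrix(profile)
    conc_molar = np.stack(
        [np.asarray(hbo_um, float), np.asarray(hhb_um, float)], axis=-1
    ) * 1e-6
    dod = conc_molar @ ext.T * profile.pathlength_cm
    return dod[..., 0], dod[..., 1]


def convert_stream(
    stream: OpticalStream, baseline: BaselineRecord, profile: DeviceProfile
) -> HemoStream:
    """Full raw-intensity to concentration conversion for a stream."""
    dod = od_change(stream.intensity, baseline)
    hbo, hhb = mbll_convert(dod[..., 0], dod[..., 1], profile)
    return HemoStream(time=stream.time, hbo=hbo, hhb=hhb)


def check_saturation(
    stream: OpticalStream,
    profile: DeviceProfile,
    ceiling: float = 4000.0,
    floor: float = 1.0,
    dead_var: float = 1e-12,
    pinned_fraction: float = 0.5,
) -> dict[int, str]:
    """Per-optode signal-quality flags: ``ok``, ``saturated`` or ``dead``.

    An optode is *saturated* when more than ``pinned_fraction`` of its frames
    sit at or beyond the detector ceiling (or at/below the floor), and *dead*
    when its intensity variance falls below ``dead_var`` (a flat line, e.g. a
    disconnected channel).  Requires at least 2 s of data.
    """
    if stream.time.size == 0:
        raise ValueError("empty stream")
    if stream.time[-1] - stream.time[0] < 2.0:
        raise ValueError("need at least 2 s of data for a saturation check")
    flags: dict[int, str] = {}
    for k in range(stream.n_optodes):
        chan = stream.intensity[:, k, :]  # (n_samples, 2)
        pinned = np.mean((chan >= ceiling) | (chan <= floor), axis=0)
        if np.any(pinned > pinned_fraction):
            flags[k + 1] = "saturated"
        elif np.any(chan.var(axis=0) < dead_var):
            flags[k + 1] = "dead"
        else:
            flags[k + 1] = "ok"
    return flags
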