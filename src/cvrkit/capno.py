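"""End-tidal CO2 extraction and PetCO2 regressor construction.

Processing chain: raw capnograph trace -> per-breath end-tidal maxima ->
linear interpolation onto the volume-acquisition grid -> quadratic
detrending -> causal convolution with a canonical double-gamma hemodynamic
response function.  The HRF kernel is normalized to unit sum so the
regressor keeps mmHg units and the downstream GLM beta is %BOLD/mmHg.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gamma as gamma_dist

from .design import AcquisitionParams

__all__ = [
    "CapnoTrace",
    "PetCO2Series",
    "PetCO2Regressor",
    "HRFParams",
    "InsufficientBreathsError",
    "detect_end_tidal",
    "interpolate_to_grid",
    "detrend_quadratic",
    "canonical_hrf",
    "build_regressor",
    "block_peak_lags",
]


class InsufficientBreathsError(ValueError):
    """Raised when too few end-tidal peaks are detected to build a regressor."""


@dataclass(frozen=True)
class CapnoTrace:
    """Raw expired-CO2 partial pressure trace (mmHg vs seconds)."""

    t: np.ndarray
    co2: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        co2 = np.asarray(self.co2, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "co2", co2)
        if t.ndim != 1 or co2.ndim != 1 or t.size != co2.size:
            raise ValueError("t and co2 must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValueError("trace must contain at least 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time stamps must be strictly increasing")
        if np.any(dt >= 2.0):
            raise ValueError("sampling gaps must be < 2 s")
        if np.any(co2 < 0):
            raise ValueError("CO2 partial pressure must be >= 0 mmHg")

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class PetCO2Series:
    """Per-breath end-tidal CO2 samples (expiratory maxima)."""

    peak_times: np.ndarray
    peak_values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.peak_times, dtype=float)
        values = np.asarray(self.peak_values, dtype=float)
        object.__setattr__(self, "peak_times", times)
        object.__setattr__(self, "peak_values", values)
        if times.size != values.size:
            raise ValueError("peak_times and peak_values must have equal length")
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("peak times must be strictly increasing")
        if values.size and (np.any(values < 0) or np.any(values > 150)):
            raise ValueError("end-tidal values outside physiological bounds [0, 150] mmHg")


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF: positive lobe minus a scaled undershoot.

    Defaults are the de facto canonical parameters: peak at 6 s, undershoot
    at 16 s, unit dispersions, peak:undershoot ratio 6, truncation at 32 s.
    ``dt_s`` is the sampling step of the kernel (the acquisition TR when the
    kernel is used on the TR grid).
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_disp: float = 1.0
    under_disp: float = 1.0
    p_u_ratio: float = 6.0
    dt_s: float = 3.0
    duration_s: float = 32.0

    def __post_init__(self) -> None:
        for name in (
            "peak_delay_s",
            "undershoot_delay_s",
            "peak_disp",
            "under_disp",
            "p_u_ratio",
            "dt_s",
            "duration_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class PetCO2Regressor:
    """PetCO2 GLM regressor on the acquisition TR grid (mmHg scale)."""

    values: np.ndarray
    tr_s: float
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("regressor must be 1-D")
        if not np.all(np.isfinite(values)):
            raise ValueError("regressor must be finite")


def detect_end_tidal(
    trace: CapnoTrace,
    min_breath_interval_s: float = 2.0,
    prominence_mmHg: float = 5.0,
) -> PetCO2Series:
    """Extract per-breath end-tidal maxima from a raw capnograph trace.

    Local maxima separated by at least ``min_breath_interval_s`` with
    prominence at least ``prominence_mmHg``.  During breath holds the trace
    is flat and low, so no peaks are emitted there; the deliberate post-hold
    expiration supplies the end-of-hold PetCO2 sample.
    """
    if min_breath_interval_s <= 0:
        raise ValueError("min_breath_interval_s must be > 0")
    fs = 1.0 / float(np.median(np.diff(trace.t)))
    distance = max(1, int(round(min_breath_interval_s * fs)))
    idx, _ = find_peaks(trace.co2, distance=distance, prominence=prominence_mmHg)
    if idx.size < 3:
        raise InsufficientBreathsError(
            f"insufficient breaths: {idx.size} end-tidal peaks detected (need >= 3)"
        )
    return PetCO2Series(peak_times=trace.t[idx], peak_values=trace.co2[idx])


def interpolate_to_grid(pet: PetCO2Series, acq: AcquisitionParams) -> np.ndarray:
    """Linear interpolation of end-tidal samples onto volume midpoints.

    Grid points before the first / after the last detected breath take the
    boundary value (constant extrapolation).
    """
    if pet.peak_times.size == 0:
        raise ValueError("empty PetCO2 series")
    span = float(pet.peak_times[-1] - pet.peak_times[0])
    if span < 0.5 * acq.scan_duration_s:
        raise ValueError(
            f"PetCO2 series spans {span:.1f} s, less than half the scan "
            f"duration ({acq.scan_duration_s:.1f} s)"
        )
    grid = acq.frame_midpoints_s()
    return np.interp(grid, pet.peak_times, pet.peak_values)


def detrend_quadratic(series: np.ndarray, t: np.ndarray | None = None) -> np.ndarray:
    """OLS residuals after removing a degree-2 polynomial in time.

    Residuals are orthogonal to {1, t, t^2} by construction.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or y.size < 4:
        raise ValueError("series must be 1-D with length >= 4")
    if t is None:
        t = np.arange(y.size, dtype=float)
    else:
        t = np.asarray(t, dtype=float)
    # centre/scale time for conditioning; spans the same column space
    tc = (t - t.mean()) / (t.max() - t.min())
    basis = np.column_stack([np.ones_like(tc), tc, tc**2])
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    return y - basis @ coef


def canonical_hrf(params: HRFParams = HRFParams()) -> np.ndarray:
    """Double-gamma HRF kernel on the ``dt_s`` grid, truncated and unit-sum.

    Unit sum means convolution preserves the amplitude (and mmHg units) of a
    sustained step, so regression coefficients stay in %BOLD/mmHg.
    """
    t = np.arange(0.0, params.duration_s + 0.5 * params.dt_s, params.dt_s)
    peak = gamma_dist.pdf(t, params.peak_delay_s / params.peak_disp, scale=params.peak_disp)
    under = gamma_dist.pdf(
        t, params.undershoot_delay_s / params.under_disp, scale=params.under_disp
    )
    kernel = peak - under / params.p_u_ratio
    total = kernel.sum()
    if total <= 0:
        raise ValueError("HRF kernel must integrate to a positive value")
    return kernel / total


def build_regressor(
    trace: CapnoTrace,
    acq: AcquisitionParams,
    hrf: HRFParams | None = None,
    min_breath_interval_s: float = 2.0,
    prominence_mmHg: float = 5.0,
) -> PetCO2Regressor:
    """Full chain: detect -> interpolate -> quadratic detrend -> cHRF convolve.

    Convolution is causal ('same' alignment): output sample k reflects the
    PetCO2 history up to volume k only.
    """
    if hrf is None:
        hrf = HRFParams(dt_s=acq.tr_s)
    elif abs(hrf.dt_s - acq.tr_s) > 1e-12:
        hrf = HRFParams(
            peak_delay_s=hrf.peak_delay_s,
            undershoot_delay_s=hrf.undershoot_delay_s,
            peak_disp=hrf.peak_disp,
            under_disp=hrf.under_disp,
            p_u_ratio=hrf.p_u_ratio,
            dt_s=acq.tr_s,
            duration_s=hrf.duration_s,
        )
    pet = detect_end_tidal(trace, min_breath_interval_s, prominence_mmHg)
    gridded = interpolate_to_grid(pet, acq)
    detrended = detrend_quadratic(gridded, acq.frame_midpoints_s())
    kernel = canonical_hrf(hrf)
    convolved = np.convolve(detrended, kernel)[: acq.n_volumes]
    provenance = {
        "n_peaks": int(pet.peak_times.size),
        "min_breath_interval_s": min_breath_interval_s,
        "prominence_mmHg": prominence_mmHg,
        "detrend": "quadratic-ols",
        "hrf": {
            "peak_delay_s": hrf.peak_delay_s,
            "undershoot_delay_s": hrf.undershoot_delay_s,
            "peak_disp": hrf.peak_disp,
            "under_disp": hrf.under_disp,
            "p_u_ratio": hrf.p_u_ratio,
            "dt_s": hrf.dt_s,
            "duration_s": hrf.duration_s,
        },
        "convolution": "causal-same",
        "tr_s": acq.tr_s,
        "n_volumes": acq.n_volumes,
    }
    return PetCO2Regressor(values=convolved, tr_s=acq.tr_s, provenance=provenance)


def block_peak_lags(
    regressor: PetCO2Regressor,
    hold_ends_s: np.ndarray | list[float],
    acq: AcquisitionParams,
    window_s: float = 14.0,
) -> np.ndarray:
    """Sub-sample lag of the regressor maximum after each breath-hold end.

    The discrete maximum within ``window_s`` after each hold end is refined
    by parabolic interpolation through its two neighbours, giving peak
    timing below the TR quantization (the TR is coarse relative to the
    hemodynamic delay).
    """
    t_grid = acq.frame_midpoints_s()
    v = regressor.values
    lags = []
    for end in np.atleast_1d(np.asarray(hold_ends_s, dtype=float)):
        win = np.where((t_grid >= end) & (t_grid <= end + window_s))[0]
        i = win[np.argmax(v[win])]
        t_peak = t_grid[i]
        if 0 < i < v.size - 1:
            y0, y1, y2 = v[i - 1], v[i], v[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:  # concave triple: refine within +/- half a TR
                t_peak += 0.5 * acq.tr_s * (y0 - y2) / denom
        lags.append(t_peak - end)
    return np.asarray(lags)
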