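"""BOLD normalization/filtering, tissue classification and volumes.

Fractional (percent) BOLD conversion, Gaussian temporal high-pass
(subtract-smoothed, FSL-like), hard tissue masks by highest probability,
probabilistic tissue volumes, and isotropic spatial smoothing in mm.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

__all__ = [
    "BoldSeries",
    "TissueMasks",
    "fractional_bold",
    "highpass_gaussian",
    "classify_tissue",
    "normalized_volume",
    "smooth_spatial",
]


@dataclass
class BoldSeries:
    """4D BOLD field (x, y, z, t) with voxel geometry and TR."""

    data: np.ndarray
    voxel_mm: tuple[float, float, float]
    tr_s: float
    units: str = "raw"  # "raw" | "percent"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4-D (x, y, z, t)")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be > 0")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class TissueMasks:
    """Mutually exclusive hard GM/WM/CSF masks (argmax of probabilities)."""

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    source: str = "argmax"

    @property
    def brain(self) -> np.ndarray:
        return self.gm | self.wm | self.csf


def fractional_bold(raw: BoldSeries) -> tuple[BoldSeries, np.ndarray]:
    """Express BOLD as percent change about each voxel's temporal mean.

    out(v, t) = 100 * (raw(v, t) - mean_t raw) / mean_t raw.

    Returns the percent series and a validity mask; voxels with nonpositive
    temporal mean cannot be expressed fractionally and are flagged invalid
    (their output is zeroed).
    """
    if raw.units == "percent":
        raise ValueError("series is already in percent units")
    mean = raw.data.mean(axis=-1)
    valid = mean > 0
    out = np.zeros_like(raw.data)
    m = mean[valid][:, None]
    out[valid] = 100.0 * (raw.data[valid] - m) / m
    pct = BoldSeries(out, raw.voxel_mm, raw.tr_s, units="percent", meta=dict(raw.meta))
    return pct, valid


def highpass_gaussian(
    series: np.ndarray, sigma_s: float, tr_s: float, axis: int = -1
) -> np.ndarray:
    """Gaussian temporal high-pass: subtract a Gaussian running mean.

    ``sigma_s`` is converted to samples via the TR; boundaries are
    reflective.  Output is zero-mean up to boundary effects.
    """
    if sigma_s <= 0:
        raise ValueError("sigma_s must be > 0")
    if sigma_s <= tr_s:
        warnings.warn(
            "high-pass sigma <= TR: filter is approximately identity-minus-self",
            stacklevel=2,
        )
    x = np.asarray(series, dtype=float)
    smoothed = gaussian_filter1d(x, sigma=sigma_s / tr_s, axis=axis, mode="reflect")
    return x - smoothed


def classify_tissue(
    prob_gm: np.ndarray,
    prob_wm: np.ndarray,
    prob_csf: np.ndarray,
    background_threshold: float = 0.05,
) -> TissueMasks:
    """Hard tissue masks: per-voxel argmax of the probability maps.

    Ties are broken in the fixed order GM > WM > CSF.  Voxels where all
    probabilities fall below ``background_threshold`` are background and
    belong to no mask.
    """
    pg, pw, pc = (np.asarray(p, dtype=float) for p in (prob_gm, prob_wm, prob_csf))
    if not (pg.shape == pw.shape == pc.shape):
        raise ValueError("probability maps must share one grid")
    stack = np.stack([pg, pw, pc])
    brain = stack.max(axis=0) >= background_threshold
    label = stack.argmax(axis=0)  # argmax returns first max: GM > WM > CSF
    return TissueMasks(
        gm=brain & (label == 0), wm=brain & (label == 1), csf=brain & (label == 2)
    )


def normalized_volume(
    prob_map: np.ndarray, voxel_mm: tuple[float, float, float], scaling: float = 1.0
) -> float:
    """Tissue volume in cm^3: scaling * voxel volume * sum of probabilities.

    ``scaling`` is the normalization to a standard intracranial volume
    (1 for synthetic subjects sharing a common grid).
    """
    p = np.asarray(prob_map, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    voxel_mm3 = float(np.prod(voxel_mm))
    return scaling * voxel_mm3 * float(p.sum()) / 1000.0


def smooth_spatial(
    map3d: np.ndarray, sigma_mm: float, voxel_mm: tuple[float, float, float]
) -> np.ndarray:
    """Isotropic Gaussian smoothing with sigma in mm (reflective boundaries)."""
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be >= 0")
    x = np.asarray(map3d, dtype=float)
    if sigma_mm == 0:
        return x.copy()
    sigmas = [sigma_mm / v for v in voxel_mm]
    return gaussian_filter(x, sigma=sigmas, mode="reflect")
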