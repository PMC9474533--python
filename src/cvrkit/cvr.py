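"""Voxel-wise GLM estimation of CVR and ROI summarization.

The CVR estimate at a voxel is the OLS coefficient of the (demeaned)
PetCO2 regressor fitted to the fractional, high-pass-filtered BOLD series:
%BOLD per mmHg of end-tidal CO2.  Tissue summaries are medians of the
beta map within the hard GM/WM masks, excluding enhancing-lesion voxels.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .capno import CapnoTrace, HRFParams, PetCO2Regressor, build_regressor
from .design import AcquisitionParams
from .preprocess import (
    BoldSeries,
    TissueMasks,
    classify_tissue,
    fractional_bold,
    highpass_gaussian,
    normalized_volume,
)

__all__ = ["CVRMap", "RoiSummary", "fit_cvr_map", "summarize_cvr", "run_subject"]


@dataclass
class CVRMap:
    """Voxel-wise CVR (beta), t-statistics and residual noise level."""

    beta: np.ndarray
    tstat: np.ndarray
    residual_sd: np.ndarray
    dof: int
    mask: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)


@dataclass
class RoiSummary:
    """Tissue-median CVR with enhancing lesions excluded from WM/GM."""

    cvr_gm: float
    cvr_wm: float
    cvr_lesion: float | None
    voxel_counts: dict[str, int]


def fit_cvr_map(
    bold_pct: BoldSeries,
    regressor: PetCO2Regressor | np.ndarray,
    mask: np.ndarray | None = None,
    confounds: Sequence[np.ndarray] | None = None,
) -> CVRMap:
    """Per-voxel OLS of percent BOLD on [regressor - mean, intercept, confounds].

    ``beta`` is the regressor coefficient in %BOLD/mmHg; ``tstat`` its
    t-statistic; ``dof`` = n_volumes - rank(design).
    """
    if bold_pct.units != "percent":
        raise ValueError("fit_cvr_map expects percent-unit BOLD")
    x = regressor.values if isinstance(regressor, PetCO2Regressor) else np.asarray(regressor, float)
    n_t = bold_pct.n_volumes
    if x.shape[0] != n_t:
        raise ValueError(
            f"regressor length {x.shape[0]} != number of volumes {n_t}"
        )
    cols = [x - x.mean(), np.ones(n_t)]
    names = ["petco2", "intercept"]
    if confounds is not None:
        for i, c in enumerate(confounds):
            c = np.asarray(c, dtype=float)
            if c.shape[0] != n_t:
                raise ValueError(f"confound {i} has length {c.shape[0]} != {n_t}")
            cols.append(c)
            names.append(f"confound_{i}")
    design = np.column_stack(cols)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {design.shape[1]} columns "
            f"{names}): some columns are collinear"
        )
    if mask is None:
        mask = np.ones(bold_pct.grid_shape, dtype=bool)
    y = bold_pct.data[mask].T  # (T, n_voxels)
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    dof = n_t - design.shape[1]
    resid_var = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(design.T @ design)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(resid_var * xtx_inv[0, 0])
        t = np.where(se > 0, coef[0] / np.where(se > 0, se, 1.0), 0.0)

    shape = bold_pct.grid_shape
    beta_map = np.zeros(shape)
    t_map = np.zeros(shape)
    sd_map = np.zeros(shape)
    beta_map[mask] = coef[0]
    t_map[mask] = t
    sd_map[mask] = np.sqrt(resid_var)
    prov = {"design_columns": names, "dof": dof}
    if isinstance(regressor, PetCO2Regressor):
        prov["regressor"] = regressor.provenance
    return CVRMap(beta=beta_map, tstat=t_map, residual_sd=sd_map, dof=dof,
                  mask=mask, provenance=prov)


def summarize_cvr(
    cvr_map: CVRMap, masks: TissueMasks, lesion_mask: np.ndarray | None = None
) -> RoiSummary:
    """Median beta within GM and WM (lesion voxels excluded) and within lesions.

    Medians use the midpoint convention for even counts (numpy default).
    ``cvr_lesion`` is None when the lesion mask is empty or absent.
    """
    if masks.gm.shape != cvr_map.beta.shape:
        raise ValueError("masks and map must share one grid")
    lesion = (
        np.zeros_like(masks.gm) if lesion_mask is None else np.asarray(lesion_mask, bool)
    )
    gm_sel = masks.gm & ~lesion & cvr_map.mask
    wm_sel = masks.wm & ~lesion & cvr_map.mask
    if not gm_sel.any() or not wm_sel.any():
        raise ValueError("empty GM or WM mask after lesion exclusion")
    lesion_sel = lesion & cvr_map.mask
    cvr_lesion = float(np.median(cvr_map.beta[lesion_sel])) if lesion_sel.any() else None
    return RoiSummary(
        cvr_gm=float(np.median(cvr_map.beta[gm_sel])),
        cvr_wm=float(np.median(cvr_map.beta[wm_sel])),
        cvr_lesion=cvr_lesion,
        voxel_counts={
            "gm": int(gm_sel.sum()),
            "wm": int(wm_sel.sum()),
            "lesion": int(lesion_sel.sum()),
        },
    )


def run_subject(
    bold_raw: BoldSeries,
    trace: CapnoTrace,
    prob_gm: np.ndarray,
    prob_wm: np.ndarray,
    prob_csf: np.ndarray,
    acq: AcquisitionParams,
    lesion_mask: np.ndarray | None = None,
    hrf: HRFParams | None = None,
    highpass_sigma_s: float = 60.0,
    volume_scaling: float = 1.0,
) -> dict[str, Any]:
    """Single-subject pipeline: regressor -> fractional BOLD -> high-pass ->
    GLM -> tissue medians and normalized volumes.

    The temporal high-pass is applied to both the BOLD data and the design
    regressor (matched filtering, as FEAT-style GLM tools do), so a pure
    linear response is recovered without filter-induced amplitude bias.
    Deterministic given inputs; returns the CVR map, the ROI summary,
    tissue masks and volumes.
    """
    regressor = build_regressor(trace, acq, hrf=hrf)
    pct, valid = fractional_bold(bold_raw)
    pct.data = highpass_gaussian(pct.data, highpass_sigma_s, acq.tr_s, axis=-1)
    x_filtered = highpass_gaussian(regressor.values, highpass_sigma_s, acq.tr_s)
    masks = classify_tissue(prob_gm, prob_wm, prob_csf)
    fit_mask = masks.brain & valid
    reg_f = PetCO2Regressor(
        values=x_filtered,
        tr_s=regressor.tr_s,
        provenance={**regressor.provenance, "design_highpass_sigma_s": highpass_sigma_s},
    )
    cvr_map = fit_cvr_map(pct, reg_f, mask=fit_mask)
    summary = summarize_cvr(cvr_map, masks, lesion_mask)
    volumes = {
        "vol_gm_cm3": normalized_volume(prob_gm, bold_raw.voxel_mm, volume_scaling),
        "vol_wm_cm3": normalized_volume(prob_wm, bold_raw.voxel_mm, volume_scaling),
        "vol_csf_cm3": normalized_volume(prob_csf, bold_raw.voxel_mm, volume_scaling),
    }
    return {
        "cvr_map": cvr_map,
        "summary": summary,
        "masks": masks,
        "volumes": volumes,
        "regressor": regressor,
    }
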