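"""Synthetic phantoms, capnograph traces, BOLD series and cohorts.

Everything downstream of acquisition is testable against known ground
truth: a concentric-shell head phantom with GM/WM/CSF probability maps and
optional white-matter lesions, a paced-breathing + breath-hold capnograph
trace generator, a linear BOLD forward model driven by the PetCO2
regressor and a voxel-wise true CVR field, and a cohort generator that
draws per-subject tissue CVRs from group/session distributions with a
built-in treatment "restoration" effect (on-treatment change negatively
coupled to pre-treatment level).

Generator defaults reproduce the study conditions this package targets:
5 x (16 s hold + 34 s recovery) breath-hold task, 92 volumes at TR = 3 s,
18 healthy controls and 23 patients scanned three times, group mean/SD
CVRs per tissue and session, and enhancing-lesion counts 12/8/3 with
nested persistence across sessions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .capno import CapnoTrace, PetCO2Regressor
from .design import AcquisitionParams, Paradigm
from .preprocess import BoldSeries, classify_tissue

__all__ = [
    "Phantom",
    "TruthMaps",
    "CohortSpec",
    "make_phantom",
    "make_capno_trace",
    "make_truth_maps",
    "make_bold",
    "make_cohort",
]


@dataclass
class Phantom:
    """Concentric-shell head phantom: CSF rim, GM shell, WM core."""

    prob_gm: np.ndarray
    prob_wm: np.ndarray
    prob_csf: np.ndarray
    lesion_mask: np.ndarray
    s0: np.ndarray
    voxel_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        total = self.prob_gm + self.prob_wm + self.prob_csf
        if np.any(total > 1.0 + 1e-9):
            raise ValueError("tissue probabilities must sum to <= 1 everywhere")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.prob_gm.shape


@dataclass
class TruthMaps:
    """Voxel-wise generative truth: CVR, drift polynomial, noise level."""

    cvr_true: np.ndarray  # %BOLD/mmHg
    drift_coeffs: np.ndarray | None = None  # (*grid, k) polynomial coeffs
    noise_sd: np.ndarray | float = 0.0  # fractional-signal SD

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.cvr_true)):
            raise ValueError("cvr_true must be finite")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def make_phantom(
    grid_shape: tuple[int, int, int] = (16, 16, 16),
    lesion_count: int = 0,
    seed: int = 0,
    lesion_radius_vox: int = 2,
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
) -> Phantom:
    """Concentric-shell phantom with smooth tissue boundaries.

    Normalized radius rho (1 at the brain edge) partitions the head into a
    WM core (rho < 0.55), a GM shell (0.55-0.8) and a CSF rim (0.8-1.0)
    with sigmoid transitions.  ``lesion_count`` disjoint spheres of radius
    ``lesion_radius_vox`` are placed wholly inside the WM-argmax region.
    Deterministic for a fixed seed.
    """
    if any(n < 8 for n in grid_shape):
        raise ValueError("grid_shape entries must be >= 8")
    if lesion_count < 0:
        raise ValueError("lesion_count must be >= 0")
    rng = np.random.default_rng(seed)
    coords = np.indices(grid_shape, dtype=float)
    center = (np.array(grid_shape, dtype=float) - 1.0) / 2.0
    r = np.sqrt(sum((coords[i] - center[i]) ** 2 for i in range(3)))
    brain_radius = 0.45 * min(grid_shape)
    rho = r / brain_radius

    w = 0.06  # transition width in normalized radius
    inside = _sigmoid((1.0 - rho) / w)
    f_wm = _sigmoid((0.55 - rho) / w)
    f_gm = _sigmoid((rho - 0.55) / w) * _sigmoid((0.8 - rho) / w)
    f_csf = _sigmoid((rho - 0.8) / w) * _sigmoid((1.0 - rho) / w)
    total = f_wm + f_gm + f_csf
    total = np.where(total > 0, total, 1.0)
    prob_wm = inside * f_wm / total
    prob_gm = inside * f_gm / total
    prob_csf = inside * f_csf / total
    # zero out far background so all-probs-below-threshold voxels exist
    bg = rho > 1.15
    for p in (prob_wm, prob_gm, prob_csf):
        p[bg] = 0.0

    s0 = 1000.0 * (1.0 * prob_gm + 0.85 * prob_wm + 1.1 * prob_csf)
    s0[rho > 1.15] = 0.0

    lesion_mask = np.zeros(grid_shape, dtype=bool)
    if lesion_count > 0:
        masks = classify_tissue(prob_gm, prob_wm, prob_csf)
        wm_idx = np.argwhere(masks.wm)
        # candidate centers: sphere of radius R fully inside the WM argmax mask
        R = lesion_radius_vox
        offsets = np.argwhere(np.ones((2 * R + 1,) * 3)) - R
        offsets = offsets[np.sum(offsets**2, axis=1) <= R**2]
        wm_set = {tuple(v) for v in wm_idx}
        candidates = [
            tuple(c)
            for c in wm_idx
            if all(tuple(c + o) in wm_set for o in offsets)
        ]
        chosen: list[np.ndarray] = []
        for _ in range(50):  # greedy picks can block each other; retry
            rng.shuffle(candidates)
            chosen = []
            for c in candidates:
                c = np.array(c)
                if all(np.sum((c - prev) ** 2) > (2 * R + 1) ** 2 for prev in chosen):
                    chosen.append(c)
                    if len(chosen) == lesion_count:
                        break
            if len(chosen) == lesion_count:
                break
        if len(chosen) < lesion_count:
            raise ValueError(
                f"cannot place {lesion_count} disjoint lesions of radius "
                f"{R} voxels: WM core of grid {grid_shape} admits only "
                f"{len(chosen)}"
            )
        for c in chosen:
            for o in offsets:
                lesion_mask[tuple(c + o)] = True

    return Phantom(prob_gm, prob_wm, prob_csf, lesion_mask, s0, voxel_mm)


def make_capno_trace(
    paradigm: Paradigm = Paradigm(),
    sample_hz: float = 20.0,
    baseline_petco2: float = 40.0,
    bh_rise: float = 8.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    hold_level: float = 1.0,
) -> CapnoTrace:
    """Paced-breathing + breath-hold capnograph trace.

    Each breath is a raised-cosine bump from an inspiratory trough near
    0 mmHg to an end-tidal peak: ``baseline_petco2`` during paced
    breathing, ``baseline_petco2 + bh_rise`` for the single deliberate
    expiration immediately after each hold.  During holds the trace sits
    flat at ``hold_level``.  Additive Gaussian noise of SD ``noise_sd``
    (mmHg), clipped at 0.
    """
    if sample_hz < 5:
        raise ValueError("sample_hz must be >= 5")
    if baseline_petco2 <= 0:
        raise ValueError("baseline_petco2 must be > 0")
    if bh_rise < 0:
        raise ValueError("bh_rise must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    total = paradigm.total_duration_s
    t = np.arange(0.0, total, 1.0 / sample_hz)
    co2 = np.full(t.size, hold_level)

    T = paradigm.breath_period_s

    def paint_breaths(start: float, end: float, first_peak: float, rest_peak: float) -> None:
        # only full breath cycles; a partial remainder stays at hold_level
        # (the pre-hold expiration to residual volume)
        b0 = start
        first = True
        while b0 + T <= end + 1e-9:
            sel = (t >= b0 - 1e-12) & (t < b0 + T - 1e-12)
            peak = first_peak if first else rest_peak
            co2[sel] = peak * 0.5 * (1.0 - np.cos(2.0 * np.pi * (t[sel] - b0) / T))
            first = False
            b0 += T

    paint_breaths(0.0, paradigm.lead_in_s, baseline_petco2, baseline_petco2)
    for onset, end in zip(paradigm.hold_onsets_s(), paradigm.hold_ends_s()):
        sel = (t >= onset - 1e-12) & (t < end - 1e-12)
        co2[sel] = hold_level
        recovery_end = end + paradigm.recovery_s
        paint_breaths(end, min(recovery_end, total), baseline_petco2 + bh_rise, baseline_petco2)

    if noise_sd > 0:
        co2 = co2 + rng.normal(0.0, noise_sd, size=co2.size)
    co2 = np.clip(co2, 0.0, None)
    return CapnoTrace(t=t, co2=co2)


def make_truth_maps(
    phantom: Phantom,
    cvr_gm: float = 0.091,
    cvr_wm: float = 0.055,
    cvr_csf: float = 0.02,
    lesion_cvr: float | None = None,
    lesion_factor: float = 0.5,
    noise_sd: float | np.ndarray = 0.0,
    drift_coeffs: np.ndarray | None = None,
) -> TruthMaps:
    """Piecewise-constant true CVR by argmax tissue, with depressed lesions.

    Lesion voxels get ``lesion_cvr`` if given, else ``lesion_factor`` times
    the WM value (default half, the depressed-reactivity scenario).
    """
    masks = classify_tissue(phantom.prob_gm, phantom.prob_wm, phantom.prob_csf)
    cvr = np.zeros(phantom.grid_shape)
    cvr[masks.gm] = cvr_gm
    cvr[masks.wm] = cvr_wm
    cvr[masks.csf] = cvr_csf
    if phantom.lesion_mask.any():
        cvr[phantom.lesion_mask] = (
            lesion_cvr if lesion_cvr is not None else lesion_factor * cvr_wm
        )
    return TruthMaps(cvr_true=cvr, drift_coeffs=drift_coeffs, noise_sd=noise_sd)


def make_bold(
    phantom: Phantom,
    truth: TruthMaps,
    regressor: PetCO2Regressor,
    acq: AcquisitionParams,
    seed: int = 0,
) -> BoldSeries:
    """Linear BOLD forward model.

    y(v, t) = s0(v) * (1 + cvr_true(v)/100 * x~(t) + d(v, t) + eps(v, t))

    with x~ the regressor minus its temporal mean (mmHg), d the per-voxel
    drift polynomial on normalized time, and eps i.i.d. Gaussian with the
    per-voxel fractional SD of ``truth.noise_sd``.  The downstream GLM on
    fractional, filtered data therefore recovers ``cvr_true`` exactly in
    the noiseless, drift-free case.
    """
    if regressor.values.shape[0] != acq.n_volumes:
        raise ValueError(
            f"regressor length {regressor.values.shape[0]} != n_volumes {acq.n_volumes}"
        )
    if truth.cvr_true.shape != phantom.grid_shape:
        raise ValueError("cvr_true and phantom must share one grid")
    rng = np.random.default_rng(seed)
    x = regressor.values - regressor.values.mean()
    shape = phantom.grid_shape
    n_t = acq.n_volumes

    frac = 1.0 + (truth.cvr_true[..., None] / 100.0) * x[None, None, None, :]
    if truth.drift_coeffs is not None:
        coeffs = np.asarray(truth.drift_coeffs, dtype=float)
        if coeffs.shape[:3] != shape:
            raise ValueError("drift_coeffs and phantom must share one grid")
        tn = np.linspace(-1.0, 1.0, n_t)
        drift = np.zeros(shape + (n_t,))
        for k in range(coeffs.shape[-1]):
            drift += coeffs[..., k, None] * tn[None, None, None, :] ** k
        frac = frac + drift
    noise_sd = np.broadcast_to(np.asarray(truth.noise_sd, dtype=float), shape)
    if np.any(noise_sd > 0):
        frac = frac + noise_sd[..., None] * rng.standard_normal(shape + (n_t,))
    data = phantom.s0[..., None] * frac
    return BoldSeries(data, phantom.voxel_mm, acq.tr_s, units="raw")


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

_REFERENCE_GROUP_STATS: Mapping[tuple[str, str], tuple[float, float]] = {
    # (group-phase, tissue) -> (mean, SD) in %BOLD/mmHg
    ("hc", "gm"): (0.105, 0.026),
    ("hc", "wm"): (0.068, 0.020),
    ("ms_pre", "gm"): (0.091, 0.026),
    ("ms_pre", "wm"): (0.055, 0.020),
    ("ms_on", "gm"): (0.107, 0.027),
    ("ms_on", "wm"): (0.066, 0.019),
}


@dataclass
class CohortSpec:
    """Cohort-level generative parameters (defaults: the study conditions).

    Pre-treatment subject CVRs are drawn per tissue from the pre-treatment
    group distribution; sessions 1 and 2 add independent within-subject
    jitter (``session_sd``, subtracted in quadrature from the marginal SD so
    cross-subject session SDs match the group SDs).  On-treatment change is
    Delta_i = mean_delta + delta_slope * (pre_i - mean_pre) + eta_i with
    total SD ``delta_sd`` per tissue; delta_slope < 0 encodes the
    restoration effect (larger recovery for larger initial impairment).
    Enhancing-lesion positivity follows ``gd_positive_counts`` per session
    with nested persistence (session-3 positives within session-2 positives
    within session-1 positives).
    """

    n_hc: int = 18
    n_ms: int = 23
    sessions: int = 3
    group_stats: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(_REFERENCE_GROUP_STATS)
    )
    csf_mean: float = 0.02
    csf_sd: float = 0.005
    delta_sd: Mapping[str, float] = field(
        default_factory=lambda: {"gm": 0.030, "wm": 0.022}
    )
    delta_slope: float = -0.6
    session_sd: float = 0.008
    gd_positive_counts: tuple[int, ...] = (12, 8, 3)
    gd_lesions_range: tuple[tuple[int, int], ...] = ((1, 5), (1, 5), (1, 2))
    missing_sessions: tuple[tuple[int, int], ...] = ((1, 2), (4, 3), (9, 3))
    vol_sd_frac: float = 0.05
    vol_cvr_corr: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hc < 2 or self.n_ms < 2:
            raise ValueError("n_hc and n_ms must be >= 2")
        for key, (_, sd) in self.group_stats.items():
            if sd <= 0:
                raise ValueError(f"group SD for {key} must be > 0")
        if any(c > self.n_ms for c in self.gd_positive_counts):
            raise ValueError("gd_positive_counts entries must be <= n_ms")
        if list(self.gd_positive_counts) != sorted(self.gd_positive_counts, reverse=True):
            raise ValueError("gd_positive_counts must be non-increasing (nested persistence)")


def _cell(spec: CohortSpec, phase: str, tissue: str) -> tuple[float, float]:
    try:
        return spec.group_stats[(phase, tissue)]
    except KeyError as exc:
        raise ValueError(f"no distributional parameters for cell ({phase}, {tissue})") from exc


def make_cohort(
    spec: CohortSpec = CohortSpec(),
    paradigm: Paradigm = Paradigm(),
    acq: AcquisitionParams = AcquisitionParams(),
) -> pd.DataFrame:
    """Draw the cohort truth table: one row per subject-session.

    HC subjects have a single session; patients have ``spec.sessions``
    (sessions 1-2 pre-treatment, session 3 on-treatment).  Declared missing
    sessions are flagged ``missing`` (no data should be generated for
    them).  Columns record every generated parameter, including the latent
    pre-treatment level and the on-treatment change per tissue.
    """
    if not acq.covers(paradigm):
        raise ValueError("acquisition does not cover the task duration")
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []

    for i in range(spec.n_hc):
        row = {
            "subject": f"HC{i + 1:02d}",
            "group": "HC",
            "session": 1,
            "missing": False,
            "gd_positive": False,
            "gd_count": 0,
        }
        for tissue in ("gm", "wm"):
            mean, sd = _cell(spec, "hc", tissue)
            row[f"true_cvr_{tissue}"] = rng.normal(mean, sd)
            row[f"vol_scale_{tissue}"] = rng.normal(1.0, spec.vol_sd_frac)
        row["true_cvr_csf"] = rng.normal(spec.csf_mean, spec.csf_sd)
        rows.append(row)

    # nested enhancing-lesion positivity: a fixed ordering, prefix per session
    order = rng.permutation(spec.n_ms)
    positive_sets = [set(order[:c]) for c in spec.gd_positive_counts]
    missing = set(tuple(m) for m in spec.missing_sessions)

    for i in range(spec.n_ms):
        pre: dict[str, float] = {}
        delta: dict[str, float] = {}
        vol_scale: dict[str, float] = {}
        for tissue in ("gm", "wm"):
            pre_mean, pre_sd = _cell(spec, "ms_pre", tissue)
            on_mean, _ = _cell(spec, "ms_on", tissue)
            subj_sd = np.sqrt(max(pre_sd**2 - spec.session_sd**2, 1e-12))
            pre[tissue] = rng.normal(pre_mean, subj_sd)
            d_sd = spec.delta_sd[tissue]
            eta_sd = np.sqrt(max(d_sd**2 - (spec.delta_slope * subj_sd) ** 2, 1e-12))
            delta[tissue] = (
                (on_mean - pre_mean)
                + spec.delta_slope * (pre[tissue] - pre_mean)
                + rng.normal(0.0, eta_sd)
            )
            # GM volume couples to the pre-treatment level (atrophy with
            # poor reactivity); WM volume is uncoupled
            rho = spec.vol_cvr_corr if tissue == "gm" else 0.0
            z_pre = (pre[tissue] - pre_mean) / subj_sd
            z_ind = rng.standard_normal()
            vol_scale[tissue] = 1.0 + spec.vol_sd_frac * (
                rho * z_pre + np.sqrt(1.0 - rho**2) * z_ind
            )
        csf = rng.normal(spec.csf_mean, spec.csf_sd)
        for s in range(1, spec.sessions + 1):
            pos = s <= len(positive_sets) and i in positive_sets[s - 1]
            lo, hi = spec.gd_lesions_range[min(s - 1, len(spec.gd_lesions_range) - 1)]
            row = {
                "subject": f"MS{i + 1:02d}",
                "group": "MS",
                "session": s,
                "missing": (i, s) in missing,
                "gd_positive": bool(pos),
                "gd_count": int(rng.integers(lo, hi + 1)) if pos else 0,
            }
            for tissue in ("gm", "wm"):
                level = pre[tissue] + (delta[tissue] if s == spec.sessions else 0.0)
                row[f"true_cvr_{tissue}"] = level + rng.normal(0.0, spec.session_sd)
                row[f"pre_{tissue}"] = pre[tissue]
                row[f"delta_{tissue}"] = delta[tissue]
                row[f"vol_scale_{tissue}"] = vol_scale[tissue]
            row["true_cvr_csf"] = csf
            rows.append(row)

    return pd.DataFrame(rows)
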