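"""Cohort-scale orchestration: synthesize sessions, estimate, collect.

Bridges the cohort truth table from :mod:`cvrkit.synthetic` and the
per-subject estimation pipeline in :mod:`cvrkit.cvr`: regenerates each
non-missing session's capnograph trace and BOLD series from deterministic
per-session seeds, runs the estimation, and assembles the estimated cohort
table consumed by :mod:`cvrkit.stats`.
"""
from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import io as _io
from .cvr import run_subject
from .design import AcquisitionParams, Paradigm
from .synthetic import (
    CohortSpec,
    Phantom,
    make_bold,
    make_capno_trace,
    make_cohort,
    make_phantom,
    make_truth_maps,
)
from .capno import build_regressor

__all__ = [
    "synthesize_session",
    "run_cohort",
    "write_cohort_files",
    "run_cohort_from_files",
    "lesion_recovery_subject",
    "treatment_effect_cohort",
]


def _session_seed(base_seed: int, subject_idx: int, session: int) -> int:
    ss = np.random.SeedSequence([base_seed, subject_idx, session])
    return int(ss.generate_state(1)[0] % (2**31))


def synthesize_session(
    row: pd.Series,
    phantom: Phantom,
    paradigm: Paradigm,
    acq: AcquisitionParams,
    seed: int,
    noise_sd: float = 0.002,
    bh_rise: float = 8.0,
    trace_noise_sd: float = 1.0,
    lesion_cvr: float | None = None,
):
    """Generate (trace, bold, truth) for one cohort-table row."""
    trace = make_capno_trace(
        paradigm, bh_rise=bh_rise, noise_sd=trace_noise_sd, seed=seed
    )
    truth = make_truth_maps(
        phantom,
        cvr_gm=row["true_cvr_gm"],
        cvr_wm=row["true_cvr_wm"],
        cvr_csf=row.get("true_cvr_csf", 0.02),
        lesion_cvr=lesion_cvr,
        noise_sd=noise_sd,
    )
    regressor = build_regressor(trace, acq)
    bold = make_bold(phantom, truth, regressor, acq, seed=seed + 1)
    return trace, bold, truth


def run_cohort(
    truth_table: pd.DataFrame,
    paradigm: Paradigm = Paradigm(),
    acq: AcquisitionParams = AcquisitionParams(),
    phantom: Phantom | None = None,
    noise_sd: float = 0.002,
    bh_rise: float = 8.0,
    trace_noise_sd: float = 1.0,
    base_seed: int = 0,
    use_lesions: bool = False,
) -> pd.DataFrame:
    """Run the estimation pipeline over every non-missing session.

    Returns the estimated cohort table (subject, group, session, cvr_gm,
    cvr_wm, cvr_lesion, gd_count, vol_gm, vol_wm).  When ``use_lesions``
    the phantom lesion mask is active for lesion-positive sessions and its
    voxels carry the depressed true CVR.
    """
    if phantom is None:
        phantom = make_phantom(acq.grid_shape, voxel_mm=acq.voxel_mm)
    out_rows: list[dict[str, Any]] = []
    subjects = {s: i for i, s in enumerate(truth_table["subject"].unique())}
    for _, row in truth_table.iterrows():
        if row.get("missing", False):
            continue
        seed = _session_seed(base_seed, subjects[row["subject"]], int(row["session"]))
        lesion_active = bool(use_lesions and row.get("gd_positive", False))
        # inactive lesions carry plain WM reactivity
        trace, bold, _ = synthesize_session(
            row, phantom, paradigm, acq, seed,
            noise_sd=noise_sd, bh_rise=bh_rise, trace_noise_sd=trace_noise_sd,
            lesion_cvr=None if lesion_active else float(row["true_cvr_wm"]),
        )
        lesion_mask = phantom.lesion_mask if lesion_active else None
        res = run_subject(
            bold, trace, phantom.prob_gm, phantom.prob_wm, phantom.prob_csf,
            acq, lesion_mask=lesion_mask,
        )
        summary = res["summary"]
        out_rows.append(
            {
                "subject": row["subject"],
                "group": row["group"],
                "session": int(row["session"]),
                "cvr_gm": summary.cvr_gm,
                "cvr_wm": summary.cvr_wm,
                "cvr_lesion": summary.cvr_lesion,
                "gd_count": int(row.get("gd_count", 0)),
                # per-subject intracranial-volume normalization factor
                "vol_gm": res["volumes"]["vol_gm_cm3"] * float(row.get("vol_scale_gm", 1.0)),
                "vol_wm": res["volumes"]["vol_wm_cm3"] * float(row.get("vol_scale_wm", 1.0)),
            }
        )
    return pd.DataFrame(out_rows)


def write_cohort_files(
    spec: CohortSpec,
    out_dir: str | Path,
    paradigm: Paradigm = Paradigm(),
    acq: AcquisitionParams = AcquisitionParams(),
    noise_sd: float = 0.002,
    bh_rise: float = 8.0,
    trace_noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Materialize a cohort on disk: NIfTI volumes, capno traces, manifest.

    Writes the shared phantom probability maps and lesion mask, one BOLD
    NIfTI and capnograph TSV per non-missing session, the truth table, a
    manifest of file paths and the generation config as JSON.  Declared
    missing sessions produce no files.  Returns the truth table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = make_cohort(spec, paradigm, acq)
    phantom = make_phantom(acq.grid_shape, lesion_count=2 if any(
        truth.get("gd_positive", pd.Series(dtype=bool))) and min(acq.grid_shape) >= 24 else 0,
        seed=spec.seed, voxel_mm=acq.voxel_mm)
    for name, vol in (
        ("prob_gm", phantom.prob_gm), ("prob_wm", phantom.prob_wm),
        ("prob_csf", phantom.prob_csf),
        ("lesion_mask", phantom.lesion_mask.astype(np.uint8)),
    ):
        _io.save_nifti(out / f"{name}.nii.gz", vol, acq.voxel_mm)
    subjects = {s: i for i, s in enumerate(truth["subject"].unique())}
    manifest = []
    for _, row in truth.iterrows():
        if row["missing"]:
            continue
        seed = _session_seed(spec.seed, subjects[row["subject"]], int(row["session"]))
        lesion_active = bool(row.get("gd_positive", False)) and phantom.lesion_mask.any()
        trace, bold, _ = synthesize_session(
            row, phantom, paradigm, acq, seed,
            noise_sd=noise_sd, bh_rise=bh_rise, trace_noise_sd=trace_noise_sd,
            lesion_cvr=None if lesion_active else float(row["true_cvr_wm"]),
        )
        stem = f"{row['subject']}_s{int(row['session'])}"
        bold_path = _io.save_nifti(out / f"{stem}_bold.nii.gz", bold.data, acq.voxel_mm)
        capno_path = _io.save_capno(out / f"{stem}_capno.tsv", trace.t, trace.co2)
        manifest.append(
            {
                "subject": row["subject"],
                "group": row["group"],
                "session": int(row["session"]),
                "bold": bold_path.name,
                "capno": capno_path.name,
                "gd_positive": bool(row.get("gd_positive", False)),
            }
        )
    _io.save_table(out / "manifest.tsv", pd.DataFrame(manifest))
    _io.save_table(out / "truth_table.tsv", truth)
    _io.save_json(
        out / "generation_config.json",
        {
            "spec": {
                "n_hc": spec.n_hc, "n_ms": spec.n_ms, "sessions": spec.sessions,
                "delta_slope": spec.delta_slope, "session_sd": spec.session_sd,
                "gd_positive_counts": list(spec.gd_positive_counts),
                "gd_nested_persistence": True,
                "missing_sessions": [list(m) for m in spec.missing_sessions],
                "seed": spec.seed,
            },
            "paradigm": {
                "n_blocks": paradigm.n_blocks, "hold_s": paradigm.hold_s,
                "recovery_s": paradigm.recovery_s, "lead_in_s": paradigm.lead_in_s,
                "breath_period_s": paradigm.breath_period_s,
            },
            "acq": {
                "tr_s": acq.tr_s, "n_volumes": acq.n_volumes,
                "voxel_mm": list(acq.voxel_mm), "grid_shape": list(acq.grid_shape),
            },
            "noise_sd": noise_sd, "bh_rise": bh_rise,
            "trace_noise_sd": trace_noise_sd,
        },
    )
    return truth


def lesion_recovery_subject(
    wm_cvr: float = 0.054,
    lesion_cvr: float = 0.027,
    gm_cvr: float = 0.091,
    noise_sd: float = 0.002,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (32, 32, 32),
    lesion_count: int = 2,
    lesion_radius_vox: int = 3,
) -> dict[str, float]:
    """One lesion-bearing patient: generate, estimate, summarize.

    White-matter lesions carry a depressed true CVR; the pipeline's
    lesion-mask median (excluded from the WM median) is the quantity of
    interest.  Returns the recovered GM/WM/lesion medians and the truths.
    """
    acq = AcquisitionParams(grid_shape=grid_shape)
    paradigm = Paradigm()
    phantom = make_phantom(grid_shape, lesion_count=lesion_count, seed=seed,
                           lesion_radius_vox=lesion_radius_vox,
                           voxel_mm=acq.voxel_mm)
    trace = make_capno_trace(paradigm, bh_rise=8.0, noise_sd=1.0, seed=seed)
    truth = make_truth_maps(phantom, cvr_gm=gm_cvr, cvr_wm=wm_cvr,
                            lesion_cvr=lesion_cvr, noise_sd=noise_sd)
    regressor = build_regressor(trace, acq)
    bold = make_bold(phantom, truth, regressor, acq, seed=seed + 1)
    res = run_subject(bold, trace, phantom.prob_gm, phantom.prob_wm,
                      phantom.prob_csf, acq, lesion_mask=phantom.lesion_mask)
    s = res["summary"]
    return {
        "cvr_gm": s.cvr_gm, "cvr_wm": s.cvr_wm, "cvr_lesion": s.cvr_lesion,
        "true_wm": wm_cvr, "true_lesion": lesion_cvr,
        "n_lesion_voxels": s.voxel_counts["lesion"],
    }


def treatment_effect_cohort(
    seed: int = 0,
    n_ms: int = 20,
    delta_mean: float = 0.016,
    delta_sd: float = 0.030,
    noise_sd: float = 0.002,
) -> dict[str, float]:
    """Complete-case patient cohort for the on-vs-pre treatment effect.

    Per-subject true on-minus-pre GM change is N(delta_mean, delta_sd)
    (no restoration coupling); all three sessions are run through the
    image pipeline, the pre-treatment level is the session 1-2 average and
    the cohort mean paired GM change is returned.
    """
    base = CohortSpec()
    stats = dict(base.group_stats)
    pre_mean, pre_sd = stats[("ms_pre", "gm")]
    stats[("ms_on", "gm")] = (pre_mean + delta_mean, pre_sd)
    spec = CohortSpec(
        n_hc=2, n_ms=n_ms, group_stats=stats,
        delta_sd={"gm": delta_sd, "wm": base.delta_sd["wm"]},
        delta_slope=0.0, missing_sessions=(), seed=seed,
    )
    truth = make_cohort(spec)
    ms_truth = truth[truth.group == "MS"]
    est = run_cohort(ms_truth, noise_sd=noise_sd, base_seed=seed + 1)
    wide = est.pivot_table(index="subject", columns="session", values="cvr_gm")
    pre = wide[[1, 2]].mean(axis=1)
    delta = wide[3] - pre
    return {
        "mean_delta_gm": float(delta.mean()),
        "sd_delta_gm": float(delta.std(ddof=1)),
        "true_mean_delta": delta_mean,
        "n": int(delta.size),
    }


def run_cohort_from_files(
    data_dir: str | Path,
    acq: AcquisitionParams = AcquisitionParams(),
) -> pd.DataFrame:
    """Estimate the cohort table from a materialized cohort directory.

    Reads the manifest, the shared probability maps and lesion mask, and
    each session's BOLD NIfTI + capnograph trace; runs the per-subject
    pipeline and returns the estimated cohort table (merging the
    enhancing-lesion counts and volume normalization factors recorded in
    the truth table).
    """
    d = Path(data_dir)
    manifest = _io.load_table(d / "manifest.tsv")
    truth = _io.load_table(d / "truth_table.tsv")
    prob_gm, voxel_mm = _io.load_nifti(d / "prob_gm.nii.gz")
    prob_wm, _ = _io.load_nifti(d / "prob_wm.nii.gz")
    prob_csf, _ = _io.load_nifti(d / "prob_csf.nii.gz")
    lesion_mask, _ = _io.load_nifti(d / "lesion_mask.nii.gz")
    lesion_mask = lesion_mask > 0.5
    rows = []
    for _, m in manifest.iterrows():
        bold_data, _ = _io.load_nifti(d / m.bold)
        trace = _io.load_capno(d / m.capno)
        from .preprocess import BoldSeries

        bold = BoldSeries(bold_data, voxel_mm, acq.tr_s)
        lm = lesion_mask if bool(m.gd_positive) and lesion_mask.any() else None
        res = run_subject(bold, trace, prob_gm, prob_wm, prob_csf, acq,
                          lesion_mask=lm)
        trow = truth[
            (truth.subject == m.subject) & (truth.session == m.session)
        ].iloc[0]
        s = res["summary"]
        rows.append(
            {
                "subject": m.subject, "group": m.group, "session": int(m.session),
                "cvr_gm": s.cvr_gm, "cvr_wm": s.cvr_wm, "cvr_lesion": s.cvr_lesion,
                "gd_count": int(trow.gd_count),
                "vol_gm": res["volumes"]["vol_gm_cm3"] * float(trow.get("vol_scale_gm", 1.0)),
                "vol_wm": res["volumes"]["vol_wm_cm3"] * float(trow.get("vol_scale_wm", 1.0)),
            }
        )
    return pd.DataFrame(rows)
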