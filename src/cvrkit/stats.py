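"""Cohort-level statistical battery.

Normality screening (Lilliefors-corrected Kolmogorov-Smirnov by default),
unpaired and paired t-tests, one-way repeated-measures ANOVA across the
three sessions, Pearson correlations with Fisher z-transforms, the
pre-treatment averaging rule, and the full results bundle over a cohort
table.  Tests report uncorrected two-sided p-values; missing data are
handled listwise per test with logged exclusions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "pretreatment_average",
    "ks_normality",
    "ttest_unpaired",
    "ttest_paired",
    "ranova_oneway",
    "pearson",
    "fisher_z",
    "analyze_cohort",
]


@dataclass
class StatResult:
    """One named test outcome: statistic, dof, p, direction, n."""

    name: str
    statistic: float
    dof: Any
    p_value: float
    direction: str = ""
    n: int = 0
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p_value must lie in [0, 1]")

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "dof": self.dof,
            "p_value": self.p_value,
            "direction": self.direction,
            "n": self.n,
            **self.extra,
        }


def pretreatment_average(table: pd.DataFrame, value: str = "cvr_gm") -> pd.Series:
    """Per-patient pre-treatment level: mean of sessions 1-2.

    When one of the two pre-treatment sessions is missing the available one
    stands for the pre-treatment value; patients with neither are dropped.
    Rows flagged ``missing`` (or with NaN values) do not contribute.
    """
    ms = table[table["group"] == "MS"]
    if ms.empty:
        raise ValueError("no MS subjects in table")
    pre = ms[ms["session"].isin([1, 2])]
    if "missing" in pre.columns:
        pre = pre[~pre["missing"].astype(bool)]
    pre = pre.dropna(subset=[value])
    out = pre.groupby("subject")[value].mean()
    out.name = f"pre_{value}"
    return out


def ks_normality(sample: np.ndarray, method: str = "lilliefors") -> StatResult:
    """Kolmogorov-Smirnov test of normality.

    ``method='lilliefors'`` (default) estimates mean/SD from the sample and
    uses the Lilliefors-corrected null distribution; ``method='naive'``
    treats the fitted parameters as known (classical one-sample KS).
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise ValueError("need n >= 5 for the normality test")
    if np.std(x, ddof=1) == 0:
        raise ValueError("zero-variance sample")
    if method == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors

        d, p = lilliefors(x, dist="norm", pvalmethod="table")
    elif method == "naive":
        d, p = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return StatResult("ks_normality", float(d), x.size, float(p), n=x.size,
                      extra={"method": method})


def ttest_unpaired(a: np.ndarray, b: np.ndarray) -> StatResult:
    """Classical two-sided pooled-variance t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per sample")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero pooled variance")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    dof = a.size + b.size - 2
    direction = "a>b" if a.mean() > b.mean() else ("a<b" if a.mean() < b.mean() else "a=b")
    return StatResult("ttest_unpaired", float(t), dof, float(p), direction,
                      n=a.size + b.size)


def ttest_paired(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Two-sided paired t-test on difference scores."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need n >= 2 pairs")
    d = x - y
    if np.var(d, ddof=1) == 0:
        raise ValueError("zero variance of paired differences")
    t, p = sps.ttest_rel(x, y)
    direction = "x>y" if d.mean() > 0 else ("x<y" if d.mean() < 0 else "x=y")
    return StatResult("ttest_paired", float(t), x.size - 1, float(p), direction, n=x.size)


def ranova_oneway(wide: np.ndarray) -> StatResult:
    """One-way repeated-measures ANOVA (subjects x conditions, complete cases).

    Within-subject F with dof (k-1, (k-1)(n-1)) from the classical
    sum-of-squares decomposition; rows containing NaN are dropped and
    counted as exclusions.
    """
    w = np.asarray(wide, dtype=float)
    if w.ndim != 2:
        raise ValueError("wide must be 2-D (subjects x conditions)")
    complete = ~np.isnan(w).any(axis=1)
    dropped = int((~complete).sum())
    w = w[complete]
    n, k = w.shape
    if n < 3:
        raise ValueError("need >= 3 complete subjects")
    grand = w.mean()
    ss_cond = n * ((w.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((w.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((w - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    tiny = 1e-12 * max(ss_total, np.finfo(float).tiny)
    if ms_err <= tiny:
        f = 0.0 if ms_cond <= tiny else float("inf")
        p = 1.0 if ms_cond <= tiny else 0.0
    else:
        f = ms_cond / ms_err
        p = float(sps.f.sf(f, df_cond, df_err))
    return StatResult("ranova_oneway", float(f), (df_cond, df_err), p, n=n,
                      extra={"excluded_incomplete": dropped})


def pearson(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Pearson correlation with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    direction = "positive" if r > 0 else ("negative" if r < 0 else "zero")
    return StatResult("pearson", float(r), x.size - 2, float(p), direction, n=x.size)


def fisher_z(r: float) -> float:
    """Variance-stabilizing Fisher transform, z = atanh(r)."""
    return float(np.arctanh(r))


def _try(results: dict, log: list, name: str, fn, *args, **kwargs) -> None:
    try:
        res = fn(*args, **kwargs)
        res.name = name
        results[name] = res
    except (ValueError, KeyError) as exc:
        log.append(f"{name}: failed ({exc})")


def analyze_cohort(
    table: pd.DataFrame,
    delta_reference: str = "pre_average",
) -> dict[str, Any]:
    """Full results bundle over a cohort table.

    Runs, per tissue where applicable: normality screens; the HC vs
    pre-treatment-MS unpaired comparison; the three-session
    repeated-measures ANOVA with the session 1 vs 2 post-hoc; the
    on-vs-pre paired test; the restoration correlation (on-minus-pre change
    vs pre-treatment level); change vs change in enhancing-lesion count
    (session 3 minus session 1); CVR vs normalized tissue volume per group
    and session with Fisher z; and the lesion-vs-WM paired comparison in
    lesion-positive patients per session.  Sub-test failures are recorded
    in the exclusion log, not fatal.  ``delta_reference`` selects the
    baseline of the on-treatment change: the pre-treatment average
    (default) or session 2 alone.
    """
    df = table.copy()
    if "missing" in df.columns:
        df = df[~df["missing"].astype(bool)]
    results: dict[str, StatResult] = {}
    log: list[str] = []

    hc = df[df["group"] == "HC"]
    ms = df[df["group"] == "MS"]
    last = int(ms["session"].max()) if not ms.empty else 3

    for tissue in ("gm", "wm"):
        col = f"cvr_{tissue}"
        pre = pretreatment_average(df, col)
        on = ms[ms["session"] == last].set_index("subject")[col].dropna()

        _try(results, log, f"ks_{tissue}_hc", ks_normality, hc[col].dropna().values)
        for s in sorted(ms["session"].unique()):
            _try(results, log, f"ks_{tissue}_ms_s{s}", ks_normality,
                 ms[ms["session"] == s][col].dropna().values)

        _try(results, log, f"unpaired_{tissue}_hc_vs_ms_pre", ttest_unpaired,
             hc[col].dropna().values, pre.values)

        wide = (
            ms.pivot_table(index="subject", columns="session", values=col, dropna=False)
            .reindex(columns=sorted(ms["session"].unique()))
            .values
        )
        _try(results, log, f"ranova_{tissue}", ranova_oneway, wide)
        s12 = ms.pivot_table(index="subject", columns="session", values=col).dropna(
            subset=[1, 2]
        )
        _try(results, log, f"posthoc_paired_{tissue}_s1_vs_s2", ttest_paired,
             s12[1].values, s12[2].values)

        if delta_reference == "pre_average":
            base = pre
        elif delta_reference == "session2":
            base = ms[ms["session"] == 2].set_index("subject")[col].dropna()
        else:
            raise ValueError(f"unknown delta_reference {delta_reference!r}")
        paired = pd.concat([on, base], axis=1, keys=["on", "pre"]).dropna()
        n_dropped = len(set(on.index) | set(base.index)) - len(paired)
        if n_dropped:
            log.append(f"paired_{tissue}_on_vs_pre: {n_dropped} subjects without both phases")
        _try(results, log, f"paired_{tissue}_on_vs_pre", ttest_paired,
             paired["on"].values, paired["pre"].values)
        delta = paired["on"] - paired["pre"]
        _try(results, log, f"corr_{tissue}_delta_vs_pre", pearson,
             paired["pre"].values, delta.values)

        if "gd_count" in df.columns:
            g1 = ms[ms["session"] == 1].set_index("subject")["gd_count"]
            g3 = ms[ms["session"] == last].set_index("subject")["gd_count"]
            dg = (g3 - g1).dropna()
            both = delta.index.intersection(dg.index)
            _try(results, log, f"corr_{tissue}_delta_vs_delta_lesions", pearson,
                 dg.loc[both].values, delta.loc[both].values)

        vol_col = f"vol_{tissue}"
        if vol_col in df.columns:
            cells = [("HC", hc[hc["session"] == 1])] + [
                (f"MS_s{s}", ms[ms["session"] == s]) for s in sorted(ms["session"].unique())
            ]
            for label, sub in cells:
                sub = sub.dropna(subset=[col, vol_col])
                key = f"corr_{tissue}_cvr_vs_vol_{label}"
                _try(results, log, key, pearson, sub[vol_col].values, sub[col].values)
                if key in results:
                    results[key].extra["fisher_z"] = fisher_z(results[key].statistic)

    if "cvr_lesion" in df.columns:
        for s in sorted(ms["session"].unique()):
            sub = ms[(ms["session"] == s)].dropna(subset=["cvr_lesion"])
            _try(results, log, f"paired_lesion_vs_wm_s{s}", ttest_paired,
                 sub["cvr_lesion"].values, sub["cvr_wm"].values)

    return {
        "results": results,
        "exclusions": log,
        "meta": {
            "p_values": "uncorrected, two-sided",
            "delta_reference": delta_reference,
            "on_session": last,
        },
    }
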