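#!/usr/bin/env python
"""Cohort-level statistics on the estimated CVR table.

Normality screens, HC vs pre-treatment-MS unpaired t-tests, the
three-session repeated-measures ANOVA with the session 1 vs 2 post-hoc,
on-vs-pre paired t-tests, the restoration correlation (change vs
pre-treatment level), change vs change in enhancing-lesion count,
lesion-vs-WM paired comparisons, and CVR vs normalized tissue volume per
group/session with Fisher z.  Writes results/cohort_stats.json and a
readable report.
"""
from pathlib import Path

from cvrkit import analyze_cohort
from cvrkit import io as ckio

ROOT = Path(__file__).resolve().parents[1] / "results"

HEADLINE = [
    "unpaired_gm_hc_vs_ms_pre",
    "unpaired_wm_hc_vs_ms_pre",
    "ranova_gm",
    "ranova_wm",
    "paired_gm_on_vs_pre",
    "paired_wm_on_vs_pre",
    "corr_gm_delta_vs_pre",
    "corr_wm_delta_vs_pre",
    "corr_gm_delta_vs_delta_lesions",
    "corr_wm_delta_vs_delta_lesions",
    "paired_lesion_vs_wm_s1",
    "corr_gm_cvr_vs_vol_MS_s1",
]


def main() -> None:
    table = ckio.load_table(ROOT / "cohort_table.tsv")
    out = analyze_cohort(table)
    results = out["results"]

    lines = ["# Cohort statistics (uncorrected two-sided p-values)", ""]
    for name, res in results.items():
        lines.append(
            f"{name}: stat={res.statistic:.4f} dof={res.dof} "
            f"p={res.p_value:.4f} dir={res.direction or '-'} n={res.n}"
        )
    lines += ["", "# Exclusions"] + (out["exclusions"] or ["none"])
    (ROOT / "cohort_stats_report.txt").write_text("\n".join(lines) + "\n")
    ckio.save_json(
        ROOT / "cohort_stats.json",
        {"results": {k: r.to_dict() for k, r in results.items()},
         "exclusions": out["exclusions"], "meta": out["meta"]},
    )

    print("headline results:")
    for name in HEADLINE:
        res = results.get(name)
        if res is None:
            print(f"  {name}: not computable on this cohort")
            continue
        star = " *" if res.p_value < 0.05 else ""
        print(f"  {name}: stat={res.statistic:+.3f}, p={res.p_value:.4f}{star}")
    print(f"wrote {ROOT / 'cohort_stats.json'} and cohort_stats_report.txt")


if __name__ == "__main__":
    main()
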