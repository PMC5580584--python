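"""The study's statistical pipeline on a loaded cohort.

Reproduces the analysis stages of the source study on any cohort table:
group and subgroup demographic summaries, one-way ANOVA of baseline GMR
across 10-year age bins, former-vs-current baseline/follow-up comparison,
per-age-bin paired t-tests within the former-smoker group, and the Spearman
correlation between age and smoking duration.  Significance is read at 5%,
two-sided, uncorrected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats import (
    GroupSummary,
    TestResult,
    one_way_anova,
    paired_t,
    spearman_rho,
)
from .types import AGE_GROUPS, CohortTable

ALPHA = 0.05

SUMMARY_VARIABLES = [
    "age",
    "smoking_duration",
    "gmr_baseline",
    "gmr_followup",
    "followup_period",
    "cessation_duration",
]


def _summarize(df: pd.DataFrame, label: str) -> list[dict]:
    out = [
        {"group": label, "variable": "n", "n": len(df), "mean": np.nan, "sd": np.nan},
        {
            "group": label,
            "variable": "males",
            "n": int((df["sex"] == "male").sum()),
            "mean": np.nan,
            "sd": np.nan,
        },
    ]
    for var in SUMMARY_VARIABLES:
        v = df[var].dropna().to_numpy(dtype=float)
        if len(v) == 0:
            out.append({"group": label, "variable": var, "n": 0, "mean": np.nan, "sd": np.nan})
            continue
        s = GroupSummary.from_values(label, v)
        out.append(
            {"group": label, "variable": var, "n": s.n, "mean": s.mean, "sd": s.sd}
        )
    return out


@dataclass
class StudyReport:
    """All tables, test results and (optional) figures of one analysis run."""

    group_summary: pd.DataFrame  # Table-1 style: former / current / total
    subgroup_summary: pd.DataFrame  # Table-2 style: status x age bin
    baseline_anova: TestResult
    age_duration_spearman: TestResult
    group_paired: dict[str, Optional[TestResult]]  # status -> baseline vs follow-up
    former_bin_paired: dict[str, Optional[TestResult]]  # age bin -> paired t (former)
    bin_means: pd.DataFrame  # mean GMR per status x bin x visit
    figures: dict[str, "plt.Figure"] = field(default_factory=dict)

    def test_results_json(self) -> dict:
        def tr(t: Optional[TestResult]) -> Optional[dict]:
            if t is None:
                return None
            return {
                "name": t.name,
                "value": t.value,
                "df": list(t.df),
                "p_value": t.p_value,
                "significant": (t.p_value is not None and t.p_value < ALPHA),
                "degenerate": t.degenerate,
            }

        return {
            "alpha": ALPHA,
            "baseline_anova_by_age_group": tr(self.baseline_anova),
            "age_vs_smoking_duration_spearman": tr(self.age_duration_spearman),
            "baseline_vs_followup_by_group": {
                k: tr(v) for k, v in self.group_paired.items()
            },
            "former_baseline_vs_followup_by_age_group": {
                k: tr(v) for k, v in self.former_bin_paired.items()
            },
        }

    def save(self, out_dir: str | Path) -> list[Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in [
            ("group_summary.csv", self.group_summary),
            ("subgroup_summary.csv", self.subgroup_summary),
            ("bin_means.csv", self.bin_means),
        ]:
            path = out / name
            df.to_csv(path, index=False, float_format="%.6g")
            written.append(path)
        path = out / "test_results.json"
        path.write_text(
            json.dumps(self.test_results_json(), indent=2, sort_keys=True) + "\n"
        )
        written.append(path)
        for name, fig in self.figures.items():
            path = out / f"{name}.png"
            fig.savefig(path, dpi=100)
            written.append(path)
        return written


def run_study_analysis(cohort: CohortTable, make_plots: bool = True) -> StudyReport:
    """Run every analysis stage on ``cohort`` and collect a report.

    Empty cells are reported with n = 0 and no test result rather than being
    dropped.
    """
    df = cohort.subjects

    rows = []
    for status in ("former", "current"):
        rows += _summarize(df[df["smoking_status"] == status], status)
    rows += _summarize(df, "total")
    group_summary = pd.DataFrame(rows)

    sub_rows = []
    for status in ("former", "current"):
        for bin_ in AGE_GROUPS:
            cell = df[(df["smoking_status"] == status) & (df["age_group"] == bin_)]
            for r in _summarize(cell, f"{status}:{bin_}"):
                r["smoking_status"] = status
                r["age_group"] = bin_
                sub_rows.append(r)
    subgroup_summary = pd.DataFrame(sub_rows)

    # baseline GMR across age bins, all subjects pooled (ANOVA)
    bins_present = [b for b in AGE_GROUPS if (df["age_group"] == b).any()]
    anova_groups = [
        df.loc[df["age_group"] == b, "gmr_baseline"].to_numpy() for b in bins_present
    ]
    baseline_anova = one_way_anova(anova_groups)

    spearman = spearman_rho(df["age"].to_numpy(), df["smoking_duration"].to_numpy())

    group_paired: dict[str, Optional[TestResult]] = {}
    for status in ("former", "current"):
        g = df[df["smoking_status"] == status]
        group_paired[status] = (
            paired_t(g["gmr_baseline"], g["gmr_followup"]) if len(g) >= 2 else None
        )

    former = df[df["smoking_status"] == "former"]
    former_bin_paired: dict[str, Optional[TestResult]] = {}
    for bin_ in AGE_GROUPS:
        cell = former[former["age_group"] == bin_]
        former_bin_paired[bin_] = (
            paired_t(cell["gmr_baseline"], cell["gmr_followup"])
            if len(cell) >= 2
            else None
        )

    mean_rows = []
    for status in ("former", "current"):
        for bin_ in AGE_GROUPS:
            cell = df[(df["smoking_status"] == status) & (df["age_group"] == bin_)]
            for visit, col in (("baseline", "gmr_baseline"), ("followup", "gmr_followup")):
                mean_rows.append(
                    {
                        "smoking_status": status,
                        "age_group": bin_,
                        "visit": visit,
                        "n": len(cell),
                        "mean_gmr": float(cell[col].mean()) if len(cell) else np.nan,
                        "sd_gmr": float(cell[col].std(ddof=1)) if len(cell) > 1 else np.nan,
                    }
                )
    bin_means = pd.DataFrame(mean_rows)

    report = StudyReport(
        group_summary=group_summary,
        subgroup_summary=subgroup_summary,
        baseline_anova=baseline_anova,
        age_duration_spearman=spearman,
        group_paired=group_paired,
        former_bin_paired=former_bin_paired,
        bin_means=bin_means,
    )
    if make_plots:
        report.figures = _make_figures(df, bin_means, former_bin_paired)
    return report


def _make_figures(df, bin_means, former_bin_paired):
    figures = {}

    # mean baseline GMR by age bin, all subjects
    fig, ax = plt.subplots(figsize=(6, 4))
    means = [
        df.loc[df["age_group"] == b, "gmr_baseline"].mean() for b in AGE_GROUPS
    ]
    ax.bar(range(len(AGE_GROUPS)), means, color="#666699")
    ax.set_xticks(range(len(AGE_GROUPS)), AGE_GROUPS)
    ax.set_xlabel("age group (years)")
    ax.set_ylabel("mean baseline GMR (%)")
    ax.set_title("Baseline GMR by age group")
    figures["gmr_by_age_group"] = fig

    # former vs current, baseline vs follow-up
    fig, ax = plt.subplots(figsize=(6, 4))
    width = 0.35
    for i, visit in enumerate(("baseline", "followup")):
        vals = [
            bin_means[
                (bin_means["smoking_status"] == status) & (bin_means["visit"] == visit)
            ]["mean_gmr"].mean()
            for status in ("former", "current")
        ]
        ax.bar(np.arange(2) + (i - 0.5) * width, vals, width, label=visit)
    ax.set_xticks([0, 1], ["former", "current"])
    ax.set_ylabel("mean GMR (%)")
    ax.set_title("GMR at baseline and follow-up by smoking status")
    ax.legend()
    figures["gmr_by_status_visit"] = fig

    # former smokers: baseline vs follow-up per age bin, with significance stars
    fig, ax = plt.subplots(figsize=(7, 4))
    xs = np.arange(len(AGE_GROUPS))
    sub = bin_means[bin_means["smoking_status"] == "former"]
    for i, visit in enumerate(("baseline", "followup")):
        vals = [
            sub[(sub["age_group"] == b) & (sub["visit"] == visit)]["mean_gmr"].iloc[0]
            for b in AGE_GROUPS
        ]
        ax.bar(xs + (i - 0.5) * width, vals, width, label=visit)
    for i, b in enumerate(AGE_GROUPS):
        t = former_bin_paired.get(b)
        if t is not None and t.p_value is not None and t.p_value < ALPHA:
            top = sub[sub["age_group"] == b]["mean_gmr"].max()
            if np.isfinite(top):
                ax.text(i, top * 1.02 + 0.5, "*", ha="center", fontsize=14)
    ax.set_xticks(xs, AGE_GROUPS)
    ax.set_xlabel("age group (years)")
    ax.set_ylabel("mean GMR (%)")
    ax.set_title("Former smokers: GMR change by age group (* p < 0.05)")
    ax.legend()
    figures["former_change_by_age_group"] = fig
    return figures
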