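"""Carcass-trait comparisons and qPCR relative expression.

Two small statistical utilities used around the sequencing analysis: a
two-group t-test recomputed from published summary statistics
(mean ± SD, n per group), defaulting to the Welch unequal-variance form,
and Livak 2^-ddCt relative quantification of qPCR cycle thresholds against
a reference gene and a calibrator group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "TraitSummary",
    "TTestResult",
    "welch_t_from_summary",
    "ddct_relative_expression",
]


@dataclass(frozen=True)
class GroupSummary:
    group: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"group {self.group}: sd must be >= 0")
        if self.n < 2:
            raise ValueError(f"group {self.group}: need n >= 2")


@dataclass(frozen=True)
class TraitSummary:
    """mean ± SD summaries of one trait for exactly two groups."""

    trait: str
    group1: GroupSummary
    group2: GroupSummary


@dataclass(frozen=True)
class TTestResult:
    trait: str
    t: float
    df: float
    p_value: float


def welch_t_from_summary(summary: TraitSummary, pooled: bool = False) -> TTestResult:
    """Two-sided t-test of group1 - group2 from summary statistics.

    Welch by default (the R ``t.test`` default): t = (m1 - m2) /
    sqrt(s1^2/n1 + s2^2/n2) with Welch–Satterthwaite degrees of freedom.
    ``pooled=True`` gives the equal-variance form (same t when n1 = n2,
    different df). Two groups with zero spread and equal means give t = 0,
    p = 1.
    """
    g1, g2 = summary.group1, summary.group2
    v1 = g1.sd**2 / g1.n
    v2 = g2.sd**2 / g2.n
    if v1 + v2 == 0:
        if g1.mean == g2.mean:
            return TTestResult(summary.trait, 0.0, float(g1.n + g2.n - 2), 1.0)
        return TTestResult(
            summary.trait,
            float(np.inf) if g1.mean > g2.mean else float(-np.inf),
            float(g1.n + g2.n - 2),
            0.0,
        )
    if pooled:
        sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / (
            g1.n + g2.n - 2
        )
        t = (g1.mean - g2.mean) / np.sqrt(sp2 * (1 / g1.n + 1 / g2.n))
        df = float(g1.n + g2.n - 2)
    else:
        t = (g1.mean - g2.mean) / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (
            v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1)
        )
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(summary.trait, float(t), float(df), float(p))


def ddct_relative_expression(
    table: pd.DataFrame, calibrator_group: str
) -> pd.DataFrame:
    """Livak 2^-ddCt relative expression per sample.

    ``table`` needs columns sample_id, group, target_ct, reference_ct and
    optionally replicate; replicate Cts are averaged per sample first.
    dCt = target - reference per sample; ddCt subtracts the calibrator
    group's mean dCt (which therefore averages to exactly 0 in that
    group); relative expression = 2^-ddCt. Note the calibrator group's
    *mean relative expression* need not be exactly 1 — 2^-ddCt averages
    geometrically, not arithmetically.
    """
    required = {"sample_id", "group", "target_ct", "reference_ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if table["reference_ct"].isna().any():
        bad = table.loc[table["reference_ct"].isna(), "sample_id"].iloc[0]
        raise ValueError(f"missing reference-gene Ct for sample {bad}")
    if (table["target_ct"] <= 0).any() or (table["reference_ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    per_sample = (
        table.groupby(["sample_id", "group"], sort=False)[
            ["target_ct", "reference_ct"]
        ]
        .mean()
        .reset_index()
    )
    if calibrator_group not in set(per_sample["group"]):
        raise ValueError(f"calibrator group {calibrator_group!r} not present")
    per_sample["dct"] = per_sample["target_ct"] - per_sample["reference_ct"]
    calibrator_mean = per_sample.loc[
        per_sample["group"] == calibrator_group, "dct"
    ].mean()
    per_sample["ddct"] = per_sample["dct"] - calibrator_mean
    per_sample["relative_expression"] = 2.0 ** (-per_sample["ddct"])
    return per_sample


def group_expression_summary(per_sample: pd.DataFrame) -> pd.DataFrame:
    """Group mean ± SEM of relative expression, for bar-plot style reporting."""
    g = per_sample.groupby("group", sort=False)["relative_expression"]
    return pd.DataFrame(
        {
            "mean": g.mean(),
            "sem": g.sem(),
            "n": g.size(),
        }
    ).reset_index()
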