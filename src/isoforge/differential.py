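"""Negative-binomial differential testing for isoform and peak counts.

A single simplified NB engine serves both applications: median-of-ratios
size factors, per-feature method-of-moments dispersion with decile-trend
shrinkage, and a two-sided Wald test of the group effect in a log-link NB
GLM fitted by IRLS (vectorised across features). Isoform calls use the
|FC| > 2 and FDR < 0.05 rule; differential peaks use FDR < 0.05 with any
nonzero enrichment. Exact numerical parity with DESeq2/DiffBind is a
non-goal; those tools' empirical-Bayes dispersion machinery is replaced by
the documented halfway decile shrinkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "DifferentialResult",
    "size_factors",
    "nb_test",
    "bh_adjust",
    "call_deis",
    "call_differential_peaks",
    "differential_analysis",
]


@dataclass
class CountMatrix:
    """Non-negative integer counts, features x samples, with two groups."""

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    group_labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("counts shape must be (n_features, n_samples)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.group_labels) != len(self.sample_ids):
            raise ValueError("one group label per sample required")
        if len(set(self.group_labels)) != 2:
            raise ValueError("exactly two distinct groups required")

    @property
    def groups(self) -> tuple[str, str]:
        """The two group names, first-appearance order (group1, group2)."""
        seen: list[str] = []
        for g in self.group_labels:
            if g not in seen:
                seen.append(g)
        return seen[0], seen[1]

    def group_masks(self) -> tuple[np.ndarray, np.ndarray]:
        g1, g2 = self.groups
        labels = np.asarray(self.group_labels)
        return labels == g1, labels == g2

    def to_tsv(self, counts_path: str, groups_path: str) -> None:
        df = pd.DataFrame(
            self.counts, index=self.feature_ids, columns=self.sample_ids
        )
        df.to_csv(counts_path, sep="\t", index_label="feature_id")
        pd.DataFrame(
            {"sample_id": self.sample_ids, "group": self.group_labels}
        ).to_csv(groups_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path: str, groups_path: str) -> "CountMatrix":
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
        groups = pd.read_csv(groups_path, sep="\t")
        order = {s: g for s, g in zip(groups["sample_id"], groups["group"])}
        return cls(
            feature_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            counts=df.to_numpy(),
            group_labels=[order[str(c)] for c in df.columns],
        )


@dataclass
class DifferentialResult:
    feature_id: str
    base_mean: float
    log2_fold_change: float
    p_value: float
    fdr: float = np.nan
    significant: bool = False


def size_factors(
    matrix: CountMatrix, pseudo_reference: bool = False
) -> np.ndarray:
    """Median-of-ratios normalisation factors, one positive real per sample.

    The reference is the per-feature geometric mean over samples, with
    features containing any zero excluded; each sample's factor is the
    median ratio of its counts to that reference. When no feature is
    positive in every sample, pass ``pseudo_reference=True`` to compute the
    geometric mean over the positive entries only.
    """
    counts = matrix.counts.astype(float)
    all_positive = np.all(counts > 0, axis=1)
    if not pseudo_reference:
        if not np.any(all_positive):
            raise ValueError(
                "no feature has nonzero counts in every sample; re-run with "
                "pseudo_reference=True to use a positive-entry geometric mean"
            )
        sub = counts[all_positive]
        geomean = np.exp(np.mean(np.log(sub), axis=1))
        ratios = sub / geomean[:, None]
    else:
        any_positive = np.any(counts > 0, axis=1)
        sub = counts[any_positive]
        with np.errstate(divide="ignore"):
            logc = np.where(sub > 0, np.log(sub), np.nan)
        geomean = np.exp(np.nanmean(logc, axis=1))
        ratios = np.where(sub > 0, sub / geomean[:, None], np.nan)
    factors = np.nanmedian(ratios, axis=0)
    if np.any(~np.isfinite(factors)) or np.any(factors <= 0):
        raise ValueError("degenerate size factors; check the count matrix")
    return factors


def _mom_dispersion(norm: np.ndarray, m1: np.ndarray, m2: np.ndarray,
                    mask1: np.ndarray, mask2: np.ndarray) -> np.ndarray:
    """Per-feature method-of-moments NB dispersion from normalised counts.

    Uses the pooled within-group variance so a true group effect does not
    inflate dispersion; alpha solves var = mu + alpha * mu^2.
    """
    n1, n2 = mask1.sum(), mask2.sum()
    v1 = np.var(norm[:, mask1], axis=1, ddof=1)
    v2 = np.var(norm[:, mask2], axis=1, ddof=1)
    pooled_var = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    grand = (n1 * m1 + n2 * m2) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - grand) / np.square(grand)
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    return np.maximum(alpha, 1e-8)


def _shrink_dispersion(alpha: np.ndarray, base_mean: np.ndarray) -> np.ndarray:
    """Halfway shrinkage toward the mean dispersion of the expression decile."""
    expressed = base_mean > 0
    if expressed.sum() < 2:
        return alpha
    shrunk = alpha.copy()
    ranks = stats.rankdata(base_mean[expressed], method="average")
    decile = np.minimum((10 * (ranks - 1) / len(ranks)).astype(int), 9)
    sub = alpha[expressed]
    trend = np.array([
        sub[decile == d].mean() if np.any(decile == d) else np.nan
        for d in range(10)
    ])
    # empty deciles inherit the global mean
    trend = np.where(np.isfinite(trend), trend, sub.mean())
    shrunk[expressed] = 0.5 * sub + 0.5 * trend[decile]
    return np.maximum(shrunk, 1e-8)


def _nb_wald_vectorized(
    counts: np.ndarray,
    factors: np.ndarray,
    x: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """IRLS fit of log(mu) = b0 + b1*x + log(s) per feature; returns (b1, se)."""
    n_feat = counts.shape[0]
    offset = np.log(factors)[None, :]
    # moment-based start values
    s1 = factors[x == 0].sum()
    s2 = factors[x == 1].sum()
    mu1 = (counts[:, x == 0].sum(axis=1) + 0.5) / s1
    mu2 = (counts[:, x == 1].sum(axis=1) + 0.5) / s2
    b0 = np.log(mu1)
    b1 = np.log(mu2) - np.log(mu1)
    xb = x[None, :]
    a = alpha[:, None]
    for _ in range(max_iter):
        eta = np.clip(b0[:, None] + b1[:, None] * xb + offset, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + a * mu)
        z = (eta - offset) + (counts - mu) / mu
        sw = w.sum(axis=1)
        swx = (w * xb).sum(axis=1)
        swx2 = (w * xb * xb).sum(axis=1)
        swz = (w * z).sum(axis=1)
        swxz = (w * xb * z).sum(axis=1)
        det = sw * swx2 - swx * swx
        det = np.where(det > 1e-300, det, np.nan)
        new_b0 = (swx2 * swz - swx * swxz) / det
        new_b1 = (sw * swxz - swx * swz) / det
        new_b0 = np.where(np.isfinite(new_b0), new_b0, b0)
        new_b1 = np.where(np.isfinite(new_b1), new_b1, b1)
        # guard against runaway separation when one group is all zeros
        new_b0 = np.clip(new_b0, -25.0, 25.0)
        new_b1 = np.clip(new_b1, -25.0, 25.0)
        delta = np.max(
            np.abs(new_b0 - b0) + np.abs(new_b1 - b1)
        ) if n_feat else 0.0
        b0, b1 = new_b0, new_b1
        if delta < tol:
            break
    eta = np.clip(b0[:, None] + b1[:, None] * xb + offset, -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + a * mu)
    sw = w.sum(axis=1)
    swx = (w * xb).sum(axis=1)
    swx2 = (w * xb * xb).sum(axis=1)
    det = sw * swx2 - swx * swx
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = sw / det
    se = np.sqrt(np.where(var_b1 > 0, var_b1, np.inf))
    return b1, se


def nb_test(matrix: CountMatrix, factors: np.ndarray) -> list[DifferentialResult]:
    """Per-feature NB Wald test of the group-2-vs-group-1 effect.

    Returns base mean (mean normalised count), a display log2 fold change
    ``log2((m2 + 0.5) / (m1 + 0.5))`` of the normalised group means, and a
    two-sided Wald p-value from the GLM coefficient (the test uses the GLM
    estimate, not the pseudo-counted display value). Features with all-zero
    counts get p = 1 and log2FC = 0; FDR is left unset for ``bh_adjust``.
    """
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (len(matrix.sample_ids),) or np.any(factors <= 0):
        raise ValueError("need one positive size factor per sample")
    mask1, mask2 = matrix.group_masks()
    if mask1.sum() < 2 or mask2.sum() < 2:
        raise ValueError("each group needs >= 2 samples for testing")

    counts = matrix.counts.astype(float)
    norm = counts / factors[None, :]
    m1 = norm[:, mask1].mean(axis=1)
    m2 = norm[:, mask2].mean(axis=1)
    base_mean = norm.mean(axis=1)
    log2fc = np.log2((m2 + 0.5) / (m1 + 0.5))

    alpha = _mom_dispersion(norm, m1, m2, mask1, mask2)
    alpha = _shrink_dispersion(alpha, base_mean)

    nonzero = counts.sum(axis=1) > 0
    p = np.ones(counts.shape[0])
    if np.any(nonzero):
        x = mask2.astype(float)
        b1, se = _nb_wald_vectorized(
            counts[nonzero], factors, x, alpha[nonzero]
        )
        z = np.where(np.isfinite(se) & (se > 0), b1 / se, 0.0)
        p[nonzero] = 2.0 * stats.norm.sf(np.abs(z))
    log2fc = np.where(nonzero, log2fc, 0.0)

    return [
        DifferentialResult(
            feature_id=fid,
            base_mean=float(bm),
            log2_fold_change=float(fc),
            p_value=float(pv),
        )
        for fid, bm, fc, pv in zip(matrix.feature_ids, base_mean, log2fc, p)
    ]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def _attach_fdr(results: list[DifferentialResult]) -> None:
    fdrs = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, fdrs):
        r.fdr = float(q)


def call_deis(
    results: list[DifferentialResult],
    min_fc: float = 2.0,
    max_fdr: float = 0.05,
) -> list[DifferentialResult]:
    """Differentially expressed isoforms: |FC| > min_fc and FDR < max_fdr.

    Both directions count; ``significant`` is set on every result in place
    and the significant subset is returned.
    """
    if min_fc <= 1:
        raise ValueError("min_fc must exceed 1")
    cut = np.log2(min_fc)
    for r in results:
        if np.isnan(r.fdr):
            raise ValueError("fdr not populated; run bh_adjust first")
        r.significant = bool(abs(r.log2_fold_change) > cut and r.fdr < max_fdr)
    return [r for r in results if r.significant]


def call_differential_peaks(
    results: list[DifferentialResult],
    max_fdr: float = 0.05,
    min_fold: float = 0.0,
) -> tuple[list[DifferentialResult], list[DifferentialResult]]:
    """Differential peaks: FDR < max_fdr with |log2FC| > min_fold.

    Returns (up-regulated, down-regulated) by the sign of the fold change;
    a fold change of exactly zero is never differential.
    """
    up, down = [], []
    for r in results:
        if np.isnan(r.fdr):
            raise ValueError("fdr not populated; run bh_adjust first")
        r.significant = bool(
            r.fdr < max_fdr and abs(r.log2_fold_change) > min_fold
        )
        if r.significant:
            (up if r.log2_fold_change > 0 else down).append(r)
    return up, down


def differential_analysis(
    matrix: CountMatrix, pseudo_reference: bool = False
) -> list[DifferentialResult]:
    """size_factors -> nb_test -> bh_adjust, returning FDR-annotated results."""
    factors = size_factors(matrix, pseudo_reference=pseudo_reference)
    results = nb_test(matrix, factors)
    _attach_fdr(results)
    return results


def results_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    """Volcano-ready table: base_mean, log2FC, p, FDR, significance flag."""
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "base_mean": [r.base_mean for r in results],
            "log2_fold_change": [r.log2_fold_change for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "significant": [r.significant for r in results],
        }
    )
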