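"""Normalization and differential calling for trio count matrices.

Normalization is median-of-ratios: each sample is scaled by the median over
features of count / (per-feature geometric mean across samples), features
with any zero count excluded from the reference. The built-in caller is a
per-feature negative-binomial Wald test on normalized counts with
method-of-moments dispersion; an externally produced differential table in
the same TSV dialect can be slotted in instead (the stage is pluggable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ROLES = ("maternal", "paternal", "hybrid")
DISPERSION_FLOOR = 1e-8


@dataclass
class TrioCountMatrix:
    """Feature x sample counts with a sample design.

    ``design`` is indexed by sample_id with columns genotype_role
    (maternal | paternal | hybrid), stage, replicate.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.design.index) - set(self.counts.columns)
        if missing:
            raise ValueError(f"design samples absent from count matrix: {sorted(missing)}")
        roles = set(self.design["genotype_role"])
        if not set(ROLES) <= roles:
            raise ValueError(f"every genotype role required, got {sorted(roles)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    def samples(self, genotype_role: str | None = None, stage: str | None = None) -> list[str]:
        sel = self.design
        if genotype_role is not None:
            sel = sel[sel["genotype_role"] == genotype_role]
        if stage is not None:
            sel = sel[sel["stage"] == stage]
        return list(sel.index)

    @property
    def stages(self) -> list[str]:
        return sorted(self.design["stage"].unique())


def filter_zero_features(counts: pd.DataFrame) -> pd.DataFrame:
    """Drop features with zero counts in every sample."""
    return counts.loc[counts.sum(axis=1) > 0]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Raises when no feature is nonzero in all samples; a pseudo-reference
    fallback is deliberately not applied silently.
    """
    arr = counts.to_numpy(dtype=float)
    full = (arr > 0).all(axis=1)
    if not full.any():
        raise ValueError(
            "no feature with nonzero counts in all samples; supply a "
            "pseudo-reference or prefiltered matrix explicitly"
        )
    ref = arr[full]
    log_geo = np.log(ref).mean(axis=1, keepdims=True)
    ratios = ref / np.exp(log_geo)
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def _mom_dispersion(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Per-feature method-of-moments NB dispersion pooled over both groups.

    alpha solves var = mu + alpha*mu^2 per group; the two estimates are
    averaged and floored at DISPERSION_FLOOR (no shrinkage).
    """
    ests = []
    for x in (x1, x2):
        mu = x.mean(axis=1)
        var = x.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (var - mu) / mu**2
        a[~np.isfinite(a)] = 0.0
        ests.append(a)
    return np.maximum((ests[0] + ests[1]) / 2, DISPERSION_FLOOR)


def call_de(
    matrix: TrioCountMatrix,
    contrast: tuple[str, str],
    stage: str,
    alpha: float = 0.05,
    norm: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """NB Wald differential test between two genotype roles within a stage.

    The Wald statistic on the log mean difference uses delta-method standard
    errors with NB variance mu + alpha*mu^2 and is referred to a t
    distribution with n1 + n2 - 2 degrees of freedom (small-sample
    calibration). BH adjustment is applied across tested features.
    """
    s1 = matrix.samples(contrast[0], stage)
    s2 = matrix.samples(contrast[1], stage)
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError(f"need >=2 replicates per genotype in contrast {contrast}")
    counts = filter_zero_features(matrix.counts[matrix.samples(stage=stage)])
    if norm is None:
        norm = normalized_counts(counts)
    else:
        norm = norm.loc[counts.index]
    x1 = norm[s1].to_numpy(dtype=float)
    x2 = norm[s2].to_numpy(dtype=float)
    n1, n2 = x1.shape[1], x2.shape[1]
    mu1, mu2 = x1.mean(axis=1), x2.mean(axis=1)
    disp = _mom_dispersion(x1, x2)

    # a group mean of zero leaves the log contrast undefined; a 0.5
    # pseudo-count on the group means keeps it finite without moving
    # well-expressed features
    both_zero = (mu1 == 0) & (mu2 == 0)
    m1 = np.where(mu1 == 0, 0.5, mu1)
    m2 = np.where(mu2 == 0, 0.5, mu2)
    log2fc = np.log2(m2 / m1)
    # Var(log mu_hat) ~ (mu + a mu^2) / (n mu^2) by the delta method
    se2 = (m1 + disp * m1**2) / (n1 * m1**2) + (m2 + disp * m2**2) / (n2 * m2**2)
    wald = (np.log(m2) - np.log(m1)) / np.sqrt(se2)
    p = 2 * stats.t.sf(np.abs(wald), df=n1 + n2 - 2)
    p = np.where(both_zero, 1.0, p)
    p = np.clip(p, 0.0, 1.0)
    padj = multipletests(p, method="fdr_bh")[1]
    direction = np.where(log2fc > 0, "up", "down")
    return pd.DataFrame(
        {
            "feature_id": counts.index,
            "contrast": f"{contrast[0]}_vs_{contrast[1]}",
            "stage": stage,
            "log2fc": log2fc,
            "pvalue": p,
            "padj": padj,
            "is_de": padj < alpha,
            "direction": direction,
        }
    ).set_index("feature_id")


def de_features_any_contrast(
    matrix: TrioCountMatrix, stage: str, alpha: float = 0.05,
    norm: pd.DataFrame | None = None,
) -> tuple[set[str], dict[tuple[str, str], pd.DataFrame]]:
    """Union of features differential in any pairwise contrast at a stage."""
    contrasts = [("maternal", "hybrid"), ("paternal", "hybrid"), ("maternal", "paternal")]
    tables = {}
    de: set[str] = set()
    for c in contrasts:
        tab = call_de(matrix, c, stage, alpha=alpha, norm=norm)
        tables[c] = tab
        de |= set(tab.index[tab["is_de"]])
    return de, tables


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]
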