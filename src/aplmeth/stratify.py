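"""PCA of the signature region-beta matrix and rank-based subtype testing.

Samples are the observations and signature regions the features. Features
are mean-imputed (region mean) where missing, centered, and unit-scaled
(zero-variance regions are dropped with a warning) before a full SVD. A
deterministic sign convention orients every component so that its
largest-magnitude region loading is positive, making scores reproducible
across runs and sample orders.

Subtype separation is assessed with a Kruskal-Wallis test on the per-sample
scores (coordinates) of the first principal component, with pairwise
rank-sum tests reported unadjusted. Region "contributions" to a component
are squared-loading shares in percent, used for the top-k region report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # regions x components
    explained_variance_ratio: np.ndarray
    dropped_regions: list[str]

    @property
    def components(self) -> list[str]:
        return list(self.scores.columns)

    def contributions(self, component: str = "PC1") -> pd.Series:
        """Squared-loading share (%) of each region on one component."""
        v = self.loadings[component].to_numpy() ** 2
        return pd.Series(100.0 * v / v.sum(), index=self.loadings.index).sort_values(
            ascending=False
        )

    def top_regions(self, k: int = 30, component: str = "PC1") -> pd.DataFrame:
        contrib = self.contributions(component).head(k)
        return pd.DataFrame(
            {"region": contrib.index, "contribution_pct": contrib.to_numpy()}
        )


def pca_stratify(matrix: pd.DataFrame) -> PCAResult:
    """PCA of a regions x samples beta matrix (see module docstring).

    Requires >= 3 samples and >= 2 regions. Missing entries are imputed by
    the region mean; regions missing everywhere or with zero variance are
    dropped with a warning.
    """
    x = matrix.T  # samples x regions
    if x.shape[0] < 3:
        raise ValueError("PCA needs at least 3 samples")
    if x.shape[1] < 2:
        raise ValueError("PCA needs at least 2 regions")
    x = x.sort_index()  # sample-order invariance
    values = x.to_numpy(dtype=float)
    col_mean = np.nanmean(values, axis=0, keepdims=True)
    values = np.where(np.isnan(values), col_mean, values)
    sd = values.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = [str(c) for c in x.columns[~keep]]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance region(s)", stacklevel=2)
    values = (values[:, keep] - values[:, keep].mean(axis=0)) / sd[keep]
    if values.shape[1] < 2:
        raise ValueError("fewer than 2 informative regions after scaling")

    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(values)
    loadings = pca.components_.T  # regions x components

    # orient each component so its largest-|loading| region loads positively
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    scores = scores * flip
    loadings = loadings * flip

    names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=x.index, columns=names),
        loadings=pd.DataFrame(loadings, index=x.columns[keep], columns=names),
        explained_variance_ratio=pca.explained_variance_ratio_,
        dropped_regions=dropped,
    )


@dataclass
class KWResult:
    h_statistic: float
    p_global: float
    pairwise: dict[tuple[str, str], float]


def kruskal_subtypes(
    scores: Sequence[float], labels: Sequence[str]
) -> KWResult:
    """Kruskal-Wallis H (tie-corrected, chi-square p on k-1 df) over groups
    defined by ``labels``, plus unadjusted pairwise two-sided rank-sum tests.

    Every group needs >= 2 samples.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    groups: dict[str, np.ndarray] = {
        str(g): scores[labels == g] for g in pd.unique(labels)
    }
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    h, p = stats.kruskal(*groups.values())
    pairwise = {}
    names = sorted(groups)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pairwise[(a, b)] = float(
                stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided").pvalue
            )
    return KWResult(h_statistic=float(h), p_global=float(p), pairwise=pairwise)


def project_samples(result: PCAResult, matrix: pd.DataFrame) -> pd.DataFrame:
    """Project new samples (regions x samples matrix) onto fitted components.

    Imputation, centering and scaling reuse the fitted regions; regions absent
    from ``matrix`` are mean-imputed. Used to place validation samples into a
    discovery-fitted space as an alternative to co-decomposition.
    """
    regions = result.loadings.index
    x = matrix.reindex(regions).T  # samples x fitted regions
    values = x.to_numpy(dtype=float)
    col_mean = np.nanmean(values, axis=0, keepdims=True)
    values = np.where(np.isnan(values), col_mean, values)
    values = (values - values.mean(axis=0)) / np.where(
        values.std(axis=0) > 0, values.std(axis=0), 1.0
    )
    scores = values @ result.loadings.to_numpy()
    return pd.DataFrame(scores, index=x.index, columns=result.components)
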