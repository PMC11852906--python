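"""CIMP-like classification: variable promoter CpGs + consensus K-means.

The CpG island methylator phenotype (CIMP) splits tumors into a broadly
promoter-hypermethylated class (CIMP-H) and the rest (CIMP-L/N). Candidate
CpGs are promoter CpGs that are variable across tumors (sample SD of beta
above ``sd_threshold``) yet quiet in normals (mean beta below
``normal_mean_max``). Tumors are then partitioned by consensus clustering:
repeated K-means on sample/item subsamples, a co-clustering frequency matrix,
and a hierarchical cut of 1 - consensus into k groups. With k = 2 the cluster
with the higher mean beta over the selected CpGs is labelled CIMP-H.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .io import CpGSiteTable, SampleSheet, Tissue, position_mask, read_bed_intervals

CIMP_HIGH = "CIMP-H"
CIMP_LOW = "CIMP-L/N"


@dataclass
class CIMPConfig:
    sd_threshold: float = 0.2
    normal_mean_max: float = 0.05
    k: int = 2
    n_resamples: int = 100
    subsample_frac: float = 0.8
    seed: int = 0
    promoter_regions: str | Path | None = None
    deterministic_init: bool = False  # identical K-means init every round

    def __post_init__(self):
        if not 0 < self.subsample_frac <= 1:
            raise ValueError("subsample_frac must be in (0, 1]")
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass
class CIMPResult:
    labels: dict[str, str]  # sample -> CIMP-H / CIMP-L/N
    consensus: pd.DataFrame  # samples x samples co-clustering frequency
    selected_cpgs: list[tuple[str, int]]
    partition: dict[str, int] = field(default_factory=dict)


def select_cimp_cpgs(
    sites: CpGSiteTable,
    tumors: Sequence[str],
    normals: Sequence[str],
    config: CIMPConfig,
    promoters: Sequence[tuple[str, int, int]] | None = None,
) -> list[tuple[str, int]]:
    """Promoter CpGs with tumor SD > sd_threshold and normal mean < max.

    ``promoters`` are 1-based inclusive intervals; if omitted they are read
    from ``config.promoter_regions``. SDs use ddof=1 (sample SD).
    """
    if not tumors or not normals:
        raise ValueError("tumor and normal sample lists must be non-empty")
    if promoters is None:
        if config.promoter_regions is None:
            raise ValueError("promoter regions are required")
        promoters = read_bed_intervals(config.promoter_regions)
    in_promoter = position_mask(sites.index, list(promoters))
    beta = sites.beta()
    tumor_sd = beta[list(tumors)].std(axis=1, ddof=1).to_numpy()
    normal_mean = beta[list(normals)].mean(axis=1).to_numpy()
    keep = in_promoter & (tumor_sd > config.sd_threshold) & (normal_mean < config.normal_mean_max)
    selected = [
        (str(c), int(p))
        for c, p in zip(
            sites.index.get_level_values("chrom")[keep],
            sites.index.get_level_values("pos")[keep],
        )
    ]
    if not selected:
        raise ValueError(
            "no CpGs satisfy the CIMP selection thresholds; consider relaxing "
            "sd_threshold / normal_mean_max or widening the promoter set"
        )
    return selected


def consensus_cluster(matrix: pd.DataFrame, config: CIMPConfig) -> CIMPResult:
    """Consensus K-means over subsampled rounds (labels assigned later).

    ``matrix`` is samples x CpGs. Each round subsamples
    ceil(subsample_frac * n) samples and items without replacement and runs
    K-means (k-means++ init seeded from the round's substream, or a fixed
    seed when ``deterministic_init``). consensus(i, j) = co-cluster count /
    co-sampled count; never co-sampled pairs are mean-imputed with a warning.
    The final partition cuts average-linkage clustering of 1 - consensus
    into k groups. Fully reproducible from ``config.seed``.
    """
    n, m = matrix.shape
    if n < config.k + 1:
        raise ValueError("need at least k+1 samples")
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        col_mean = np.nanmean(values, axis=0, keepdims=True)
        values = np.where(np.isnan(values), col_mean, values)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC1]))
    n_sub = ceil(config.subsample_frac * n)
    m_sub = max(1, ceil(config.subsample_frac * m))
    co_sampled = np.zeros((n, n))
    co_clustered = np.zeros((n, n))
    for round_idx in range(config.n_resamples):
        rows = rng.choice(n, size=n_sub, replace=False)
        cols = rng.choice(m, size=m_sub, replace=False)
        km_seed = config.seed if config.deterministic_init else int(
            rng.integers(0, 2**31 - 1)
        )
        km = KMeans(n_clusters=config.k, n_init=5, random_state=km_seed)
        part = km.fit_predict(values[np.ix_(rows, cols)])
        same = part[:, None] == part[None, :]
        co_sampled[np.ix_(rows, rows)] += 1.0
        co_clustered[np.ix_(rows, rows)] += same
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = co_clustered / co_sampled
    never = co_sampled == 0
    np.fill_diagonal(never, False)
    if never.any():
        warnings.warn(
            f"{int(never.sum() // 2)} sample pair(s) never co-sampled; "
            "mean-imputing their consensus entries",
            stacklevel=2,
        )
        consensus[never] = np.nanmean(consensus[~np.eye(n, dtype=bool) & ~never])
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0

    dist = squareform(1.0 - consensus, checks=False)
    tree = linkage(dist, method="average")
    partition = fcluster(tree, t=config.k, criterion="maxclust")
    return CIMPResult(
        labels={},
        consensus=pd.DataFrame(consensus, index=matrix.index, columns=matrix.index),
        selected_cpgs=[],
        partition={s: int(c) for s, c in zip(matrix.index, partition)},
    )


def assign_cimp(result: CIMPResult, matrix: pd.DataFrame) -> CIMPResult:
    """Label the higher-mean-beta cluster CIMP-H (k = 2 partitions only)."""
    clusters = sorted(set(result.partition.values()))
    if len(clusters) != 2:
        raise ValueError(f"expected a 2-cluster partition, got {len(clusters)}")
    means = {}
    for c in clusters:
        members = [s for s, ci in result.partition.items() if ci == c]
        if not members:
            raise ValueError("degenerate clustering: empty cluster")
        means[c] = float(matrix.loc[members].to_numpy().mean())
    c_high = max(clusters, key=lambda c: means[c])
    c_low = min(clusters, key=lambda c: means[c])
    if means[c_high] == means[c_low]:
        warnings.warn("tied cluster means; labelling all samples CIMP-L/N", stacklevel=2)
        labels = {s: CIMP_LOW for s in result.partition}
    else:
        labels = {
            s: CIMP_HIGH if c == c_high else CIMP_LOW
            for s, c in result.partition.items()
        }
    result.labels = labels
    return result


def classify_cimp(
    sites: CpGSiteTable,
    samples: SampleSheet,
    config: CIMPConfig,
    promoters: Sequence[tuple[str, int, int]] | None = None,
) -> CIMPResult:
    """End-to-end CIMP assignment for a cohort's tumor samples."""
    tumors = samples.samples(tissue=Tissue.tumor)
    normals = samples.samples(tissue=Tissue.NAT)
    selected = select_cimp_cpgs(sites, tumors, normals, config, promoters)
    beta = sites.beta()
    idx = pd.MultiIndex.from_tuples(selected, names=["chrom", "pos"])
    matrix = beta.loc[idx, tumors].T  # tumors x selected CpGs
    result = consensus_cluster(matrix, config)
    result.selected_cpgs = selected
    return assign_cimp(result, matrix)
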