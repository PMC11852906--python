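"""Site-level analysis: coverage filter, SNP masking, per-CpG testing, FDR.

The comparison contract follows the cohort design: lesion vs matched normal
tissue from the same patients is tested with the paired Wilcoxon signed-rank;
comparisons across subtypes involve different patients and use the unpaired
rank-sum test. Both run vectorized over all sites (see :mod:`.ranktests`),
p-values are Benjamini-Hochberg adjusted jointly across the comparison's
sites, and a site is called significant iff p_adj < alpha AND
|delta_beta| >= min_delta.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import ranktests
from .io import CpGSiteTable, read_bed_intervals, position_mask

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Thresholds of the site- and region-level analysis.

    Defaults: coverage >= 5 reads in every sample, alpha 0.05 after BH,
    effect size |delta beta| >= 0.2, region gap <= 50 bp, >= 3 CpGs per
    region with >= 60% of them significant.
    """

    min_coverage: int = 5
    maf_mask: str | Path | None = None
    alpha: float = 0.05
    min_delta: float = 0.2
    max_gap: int = 50
    min_cpgs: int = 3
    min_sig_frac: float = 0.6

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.min_delta <= 1:
            raise ValueError("min_delta must be in [0, 1]")
        if self.min_cpgs < 1:
            raise ValueError("min_cpgs must be >= 1")
        if not 0 < self.min_sig_frac <= 1:
            raise ValueError("min_sig_frac must be in (0, 1]")


#: Columns of the site test-result table (one row per tested CpG).
SITE_RESULT_COLUMNS = [
    "chrom",
    "pos",
    "p_raw",
    "p_adj",
    "delta_beta",
    "significant",
    "untestable",
]


def filter_sites(
    sites: CpGSiteTable,
    config: AnalysisConfig,
    sample_ids: Sequence[str] | None = None,
) -> CpGSiteTable:
    """Keep CpGs covered by >= min_coverage reads in every analysis sample
    and not overlapping the SNP mask (positions with common variants).
    """
    table = sites if sample_ids is None else sites.select_samples(sample_ids)
    keep = (table.depth().to_numpy() >= config.min_coverage).all(axis=1)
    if config.maf_mask:
        intervals = read_bed_intervals(config.maf_mask)
        keep &= ~position_mask(table.index, intervals)
    if not keep.any():
        warnings.warn("no CpG sites survive filtering", stacklevel=2)
    log.info("filter_sites: %d of %d sites retained", int(keep.sum()), table.n_sites)
    return table.select_rows(keep)


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def test_sites(
    sites: CpGSiteTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
    paired: bool,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Per-CpG differential test of group A vs group B on beta values.

    If ``paired``, ``group_a[i]`` and ``group_b[i]`` must be the two tissues
    of the same patient and the signed-rank test is used; otherwise the
    rank-sum test. delta_beta = mean(A) - mean(B) (hyper in A when positive),
    ignoring missing betas. Sites with too few informative observations are
    reported with p_raw = 1 and ``untestable`` set — never dropped, so region
    CpG counts stay aligned with the filtered table.
    """
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("each group needs at least 3 samples")
    if paired and len(group_a) != len(group_b):
        raise ValueError("paired groups must align one-to-one")
    beta = sites.beta()
    a = beta[list(group_a)].to_numpy()
    b = beta[list(group_b)].to_numpy()
    if paired:
        p_raw, untestable = ranktests.signed_rank_test(a - b)
    else:
        p_raw, untestable = ranktests.rank_sum_test(a, b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN rows
        delta = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
    p_adj = adjust_bh(p_raw)
    significant = (p_adj < config.alpha) & (np.abs(delta) >= config.min_delta)
    significant &= ~untestable
    return pd.DataFrame(
        {
            "chrom": sites.index.get_level_values("chrom"),
            "pos": sites.index.get_level_values("pos"),
            "p_raw": p_raw,
            "p_adj": p_adj,
            "delta_beta": delta,
            "significant": significant,
            "untestable": untestable,
        }
    )


def write_site_results(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False)


def read_site_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
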