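"""Aggregation of per-CpG test results into differentially methylated regions.

A region is a maximal run of tested CpGs in which consecutive positions are
at most ``max_gap`` (50 bp) apart. Runs are kept as DMRs when they contain at
least ``min_cpgs`` (3) CpGs, at least ``min_sig_frac`` (60%, inclusive) of
them significant, and all significant CpGs agree in the sign of delta beta;
mixed-sign runs are discarded rather than split. Region coordinates span the
first to last CpG with no flanking padding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DMR:
    """A differentially methylated region (coordinates 1-based inclusive)."""

    chrom: str
    start: int
    end: int
    n_cpgs: int
    n_sig: int
    mean_delta: float
    direction: str  # "hyper" | "hypo"
    comparison: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("start > end")
        if self.direction not in ("hyper", "hypo"):
            raise ValueError(f"bad direction {self.direction!r}")

    @property
    def frac_significant(self) -> float:
        return self.n_sig / self.n_cpgs

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def cluster_sites(positions: Sequence[int], max_gap: int) -> list[np.ndarray]:
    """Greedy single-pass clustering of sorted unique positions.

    Consecutive positions whose coordinate difference is <= ``max_gap`` share
    a run; a difference of max_gap + 1 splits.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if pos.size == 0:
        return []
    d = np.diff(pos)
    if (d <= 0).any():
        raise ValueError("positions must be sorted ascending and unique")
    breaks = np.flatnonzero(d > max_gap) + 1
    return np.split(pos, breaks)


def call_dmrs(results: pd.DataFrame, config, comparison: str) -> list[DMR]:
    """Aggregate one comparison's site results into DMRs.

    ``results`` must contain ALL filtered sites of the comparison (significant
    or not): significance enters only through the within-run fraction, so runs
    legitimately contain non-significant CpGs.
    """
    dmrs: list[DMR] = []
    for chrom, sub in results.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        sig = sub["significant"].to_numpy(dtype=bool)
        delta = sub["delta_beta"].to_numpy(dtype=float)
        offset = 0
        for run in cluster_sites(pos, config.max_gap):
            k = len(run)
            run_sig = sig[offset : offset + k]
            run_delta = delta[offset : offset + k]
            offset += k
            n_sig = int(run_sig.sum())
            if k < config.min_cpgs or n_sig == 0:
                continue
            if n_sig / k < config.min_sig_frac:
                continue
            signs = np.sign(run_delta[run_sig])
            if len(set(signs)) != 1:
                continue  # mixed-direction run: discarded, not split
            mean_delta = float(run_delta[run_sig].mean())
            dmrs.append(
                DMR(
                    chrom=str(chrom),
                    start=int(run[0]),
                    end=int(run[-1]),
                    n_cpgs=k,
                    n_sig=n_sig,
                    mean_delta=mean_delta,
                    direction="hyper" if signs[0] > 0 else "hypo",
                    comparison=comparison,
                )
            )
    return dmrs


@dataclass
class ComparisonSummary:
    """Per-comparison DMR counts plus grand totals (Table-2-style).

    ``rows`` maps comparison -> (n_dmrs, n_hyper, n_hypo); hyper/hypo may be
    None for comparisons where direction was not assigned. Grand totals count
    every row; the hyper/hypo totals cover only rows with direction assigned.
    """

    rows: dict[str, tuple[int, int | None, int | None]]

    @property
    def total_dmrs(self) -> int:
        return sum(n for n, _, _ in self.rows.values())

    @property
    def total_hyper(self) -> int:
        return sum(h for _, h, _ in self.rows.values() if h is not None)

    @property
    def total_hypo(self) -> int:
        return sum(h for _, _, h in self.rows.values() if h is not None)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [(c, n, hyper, hypo) for c, (n, hyper, hypo) in self.rows.items()],
            columns=["comparison", "n_dmrs", "n_hyper", "n_hypo"],
        )
        df.loc[len(df)] = ["total", self.total_dmrs, self.total_hyper, self.total_hypo]
        return df

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, tuple[int, int | None, int | None]]
    ) -> "ComparisonSummary":
        for c, (n, hyper, hypo) in counts.items():
            if hyper is not None and hypo is not None and n != hyper + hypo:
                raise ValueError(f"{c}: n_dmrs != n_hyper + n_hypo")
        return cls(rows=dict(counts))


def summarize_comparisons(dmr_sets: Mapping[str, Sequence[DMR]]) -> ComparisonSummary:
    """Count DMRs (total / hyper / hypo) per comparison with grand totals."""
    rows = {}
    for comparison, dmrs in dmr_sets.items():
        n_hyper = sum(1 for d in dmrs if d.direction == "hyper")
        n_hypo = sum(1 for d in dmrs if d.direction == "hypo")
        rows[comparison] = (len(dmrs), n_hyper, n_hypo)
    return ComparisonSummary(rows=rows)
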