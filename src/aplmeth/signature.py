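"""Subtype-unique hypermethylated signature regions and derived summaries.

The signature logic mirrors the study design's region set algebra: candidate
regions come from the inter-subtype comparisons, each assigned to the subtype
on its elevated (hypermethylated) side; candidates overlapping any
lesion-vs-NAT DMR by >= 1 bp are excluded, so only differences not explained
by a lesion-vs-normal shift survive; regions claimed by two subtypes with
inconsistent assignment are dropped. Overlapping same-subtype claims from
different comparisons are merged into one region (union interval) with the
contributing comparisons kept as provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._intervals import build_interval_index, connected_groups, overlaps_any
from .io import CpGSiteTable, GenomeInfo
from .regions import DMR


@dataclass(frozen=True)
class SignatureRegion:
    """A subtype-unique hypermethylated region with its provenance."""

    chrom: str
    start: int
    end: int
    subtype: str
    comparisons: tuple[str, ...]

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class SignatureSet:
    """Per-subtype unique hypermethylated regions plus exclusion accounting."""

    regions: list[SignatureRegion]
    n_candidates: int = 0
    n_nat_excluded: int = 0
    n_ambiguous: int = 0

    def by_subtype(self, subtype: str) -> list[SignatureRegion]:
        return [r for r in self.regions if r.subtype == subtype]

    @property
    def subtypes(self) -> list[str]:
        return sorted({r.subtype for r in self.regions})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.chrom, r.start, r.end, r.subtype, ",".join(r.comparisons)) for r in self.regions],
            columns=["chrom", "start", "end", "subtype", "comparisons"],
        )


def _elevated_side(comparison: str, direction: str) -> str:
    """Subtype in which a DMR from 'X_vs_Y' is hypermethylated."""
    try:
        first, second = comparison.split("_vs_")
    except ValueError:
        raise ValueError(
            f"comparison label {comparison!r} is not of the form 'X_vs_Y'"
        ) from None
    return first if direction == "hyper" else second


def select_unique_hyper(
    inter_subtype_dmrs: Mapping[str, Sequence[DMR]],
    vs_nat_dmrs: Mapping[str, Sequence[DMR]],
) -> SignatureSet:
    """Derive the subtype-unique hypermethylated signature.

    Steps, in order: (1) pool inter-subtype DMRs as candidates, each labelled
    with its elevated side; (2) drop candidates overlapping (>= 1 bp) any
    lesion-vs-NAT DMR; (3) group mutually overlapping survivors — groups whose
    claims disagree on the subtype are dropped as ambiguous, consistent groups
    are merged into one region per component. Output order is deterministic
    (chrom, start) and independent of the order comparisons are supplied.
    """
    nat_index = build_interval_index(
        d.interval for dmrs in vs_nat_dmrs.values() for d in dmrs
    )
    candidates: list[tuple[str, int, int, str, str]] = []
    for comparison in sorted(inter_subtype_dmrs):
        for d in inter_subtype_dmrs[comparison]:
            subtype = _elevated_side(comparison, d.direction)
            candidates.append((d.chrom, d.start, d.end, subtype, comparison))

    n_candidates = len(candidates)
    survivors = [
        c for c in candidates if not overlaps_any(c[0], c[1], c[2], nat_index)
    ]
    n_nat_excluded = n_candidates - len(survivors)

    regions: list[SignatureRegion] = []
    n_ambiguous = 0
    intervals = [(c[0], c[1], c[2]) for c in survivors]
    for group in connected_groups(intervals):
        subtypes = {survivors[i][3] for i in group}
        if len(subtypes) != 1:
            n_ambiguous += len(group)
            continue
        chrom = survivors[group[0]][0]
        start = min(survivors[i][1] for i in group)
        end = max(survivors[i][2] for i in group)
        comparisons = tuple(sorted({survivors[i][4] for i in group}))
        regions.append(SignatureRegion(chrom, start, end, subtypes.pop(), comparisons))
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    return SignatureSet(
        regions=regions,
        n_candidates=n_candidates,
        n_nat_excluded=n_nat_excluded,
        n_ambiguous=n_ambiguous,
    )


def chromosome_enrichment(
    dmrs: Sequence[DMR], genome: GenomeInfo, flag_threshold: float = 1.5
) -> pd.DataFrame:
    """Length-normalized per-chromosome DMR enrichment over autosomes.

    enrichment(c) = (n_c / L_c) / (N_total / L_total), computed over autosomal
    chromosomes only; the length-weighted mean of the values is exactly 1.
    Chromosomes with enrichment > ``flag_threshold`` are flagged.
    """
    autosomes = genome.autosomes
    if not autosomes:
        raise ValueError("genome table contains no autosomes")
    counts = {c: 0 for c in autosomes}
    for d in dmrs:
        if d.chrom not in genome.lengths:
            raise ValueError(f"chromosome {d.chrom!r} absent from genome table")
        if d.chrom in counts:
            counts[d.chrom] += 1
    total_len = sum(genome.lengths[c] for c in autosomes)
    total_n = sum(counts.values())
    rows = []
    for c in autosomes:
        density = counts[c] / genome.lengths[c]
        overall = total_n / total_len
        enrich = density / overall if overall > 0 else 0.0
        rows.append((c, counts[c], genome.lengths[c], enrich, enrich > flag_threshold))
    return pd.DataFrame(
        rows, columns=["chrom", "n_dmrs", "length", "enrichment", "flagged"]
    )


def region_beta_matrix(
    regions: Sequence[SignatureRegion] | Sequence[DMR],
    sites: CpGSiteTable,
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Regions x samples matrix of mean beta over each region's CpGs.

    Entries are the unweighted mean of site betas within [start, end]; missing
    (NaN) when a sample has no covered CpG there. Regions containing zero
    tested CpGs produce an all-missing row with a warning.
    """
    if len(regions) == 0:
        raise ValueError("no regions supplied")
    beta = sites.beta()
    if sample_ids is not None:
        beta = beta[list(sample_ids)]
    chroms = sites.index.get_level_values("chrom").to_numpy()
    poss = sites.index.get_level_values("pos").to_numpy()
    rows = []
    labels = []
    for r in regions:
        in_region = (chroms == r.chrom) & (poss >= r.start) & (poss <= r.end)
        labels.append(f"{r.chrom}:{r.start}-{r.end}")
        if not in_region.any():
            warnings.warn(
                f"region {labels[-1]} contains no tested CpGs", stacklevel=2
            )
            rows.append(np.full(beta.shape[1], np.nan))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            rows.append(np.nanmean(beta.to_numpy()[in_region], axis=0))
    return pd.DataFrame(rows, index=labels, columns=beta.columns)
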