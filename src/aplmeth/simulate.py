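"""Synthetic paired tumor/NAT bisulfite cohorts with planted ground truth.

The generator emulates the cohort structure the analysis assumes — paired
tumor and normal-adjacent-tissue (NAT) samples per patient across three
precancerous-lesion subtypes — entirely from a seeded model, so every
downstream stage is testable without patient data.

Model
-----
CpGs are placed in clusters (3-8 CpGs, 10-40 bp intra-cluster gaps,
300-1500 bp between clusters) so region aggregation sees realistic geometry.
Each site has a cohort-level mean methylation m ~ Beta(alpha, beta); each
patient draws a baseline p0 ~ Beta(m*kappa, (1-m)*kappa) shared by that
patient's tumor and NAT, which induces the within-patient correlation the
paired test exploits. Read counts are depth ~ Poisson(mean_depth) and
meth ~ Binomial(depth, p) per sample per site.

Three kinds of perturbation are planted in whole CpG clusters:

* tumor-vs-NAT regions (per subtype, hyper or hypo): tumor p shifts by
  +/- planted_delta in that subtype's tumor samples only. These are the
  lesion-vs-normal DMRs the region caller should recover.
* subtype-signature regions (per subtype, hyper): the site mean shifts by
  +planted_delta in BOTH tissues of that subtype's patients (a field-effect
  style change), so they surface only in inter-subtype comparisons and
  survive the signature's vs-NAT overlap exclusion.
* a promoter panel: clusters with near-zero baseline methylation; tumors of
  CIMP-H patients gain ``cimp_delta`` there. Promoter intervals are emitted
  as a BED for the CIMP classifier.

Randomness flows from one seed through keyed substreams (geometry, patient
baselines, per-sample counts), so identical seeds give bit-identical cohorts
and adding patients does not perturb existing ones.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    APL_SUBTYPES,
    CpGSiteTable,
    GenomeInfo,
    SampleRecord,
    SampleSheet,
    Split,
    Subtype,
    Tissue,
    write_bed_intervals,
    write_bismark_cov,
    write_chrom_sizes,
    write_sample_sheet,
)

KIND_TUMOR_VS_NAT = "tumor_vs_nat"
KIND_SIGNATURE = "signature"


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults describe the desk-scale study: 10 tumor/NAT pairs per subtype at
    22.5x mean depth over 10,000 clustered CpGs, 120 planted tumor-vs-NAT
    regions per subtype (half hyper, half hypo) and 40 subtype-signature
    regions per subtype of 5 CpGs each at delta beta 0.35, and a 40% CIMP-H
    tumor fraction gaining 0.5 beta over a 30-cluster promoter panel.
    """

    n_patients_per_subtype: int = 10
    n_cpgs: int = 10_000
    n_chroms: int = 4
    chrom_length: int = 2_000_000
    mean_depth: float = 22.5
    planted_regions_per_subtype: int = 120
    hyper_fraction: float = 0.5
    signature_regions_per_subtype: int = 40
    planted_delta: float = 0.35
    region_n_cpgs: int = 5
    intra_region_gap: int = 50
    background_beta_alpha: float = 0.4
    background_beta_beta: float = 0.4
    patient_concentration: float = 60.0
    cimp_fraction: float = 0.4
    cimp_delta: float = 0.5
    n_promoter_clusters: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.mean_depth <= 5:
            raise ValueError("mean_depth must exceed the 5-read coverage floor")
        if not 0 <= self.planted_delta <= 1:
            raise ValueError("planted_delta must be in [0, 1]")
        if self.region_n_cpgs < 3:
            raise ValueError("region_n_cpgs must be >= 3")
        if self.intra_region_gap > 50:
            raise ValueError("intra_region_gap must be <= 50 bp")
        if not 0 <= self.cimp_fraction <= 1:
            raise ValueError("cimp_fraction must be in [0, 1]")


@dataclass(frozen=True)
class PlantedRegion:
    chrom: str
    start: int
    end: int
    subtype: str  # affected subtype
    direction: str  # "hyper" | "hypo"
    delta: float
    kind: str  # KIND_TUMOR_VS_NAT | KIND_SIGNATURE

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery testing."""

    regions: list[PlantedRegion] = field(default_factory=list)
    cimp_labels: dict[str, str] = field(default_factory=dict)  # tumor sample -> label
    promoters: list[tuple[str, int, int]] = field(default_factory=list)
    panel_sites: list[tuple[str, int]] = field(default_factory=list)

    def regions_of(
        self, kind: str | None = None, subtype: str | None = None,
        direction: str | None = None,
    ) -> list[PlantedRegion]:
        return [
            r
            for r in self.regions
            if (kind is None or r.kind == kind)
            and (subtype is None or r.subtype == subtype)
            and (direction is None or r.direction == direction)
        ]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "regions": [asdict(r) for r in self.regions],
            "cimp_labels": self.cimp_labels,
            "promoters": [list(p) for p in self.promoters],
            "panel_sites": [list(p) for p in self.panel_sites],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            regions=[PlantedRegion(**r) for r in payload["regions"]],
            cimp_labels=payload["cimp_labels"],
            promoters=[tuple(p) for p in payload["promoters"]],
            panel_sites=[tuple(p) for p in payload["panel_sites"]],
        )


@dataclass
class SyntheticCohort:
    sites: CpGSiteTable
    samples: SampleSheet
    truth: SyntheticTruth
    genome: GenomeInfo
    files: dict[str, Path] = field(default_factory=dict)


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


@dataclass
class _Cluster:
    chrom: str
    positions: np.ndarray  # ascending, 1-based
    index: slice  # row slice into the global site arrays

    @property
    def span(self) -> tuple[str, int, int]:
        return (self.chrom, int(self.positions[0]), int(self.positions[-1]))


def _build_geometry(config: SimulationConfig) -> tuple[list[_Cluster], pd.MultiIndex]:
    """Clustered CpG placement along each chromosome."""
    rng = _substream(config.seed, 1)
    per_chrom = np.full(config.n_chroms, config.n_cpgs // config.n_chroms)
    per_chrom[: config.n_cpgs % config.n_chroms] += 1
    clusters: list[_Cluster] = []
    chrom_arr: list[str] = []
    pos_arr: list[int] = []
    row = 0
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        remaining = int(per_chrom[ci])
        pos = 1 + int(rng.integers(100, 1000))
        while remaining > 0:
            size = min(int(rng.integers(3, 9)), remaining)
            gaps = rng.integers(10, min(41, config.intra_region_gap + 1), size=size - 1)
            positions = pos + np.concatenate([[0], np.cumsum(gaps)]).astype(np.int64)
            if positions[-1] > config.chrom_length:
                raise ValueError(
                    "infeasible geometry: CpG clusters exceed chrom_length "
                    f"({config.n_cpgs} CpGs on {config.n_chroms} x "
                    f"{config.chrom_length} bp)"
                )
            clusters.append(_Cluster(chrom, positions, slice(row, row + size)))
            chrom_arr.extend([chrom] * size)
            pos_arr.extend(positions.tolist())
            row += size
            remaining -= size
            pos = int(positions[-1]) + int(rng.integers(300, 1501))
    index = pd.MultiIndex.from_arrays(
        [np.array(chrom_arr), np.array(pos_arr, dtype=np.int64)], names=["chrom", "pos"]
    )
    return clusters, index


def generate_cohort(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SyntheticCohort:
    """Generate a cohort; optionally emit coverage files + sheet + truth.

    Identical configs (same seed) produce bit-identical count matrices. When
    ``out_dir`` is given, writes one Bismark coverage file per sample plus
    sample_sheet.tsv, truth.json, promoters.bed and chrom.sizes.
    """
    clusters, index = _build_geometry(config)
    n_sites = len(index)
    rng_assign = _substream(config.seed, 2)

    eligible = [i for i, c in enumerate(clusters) if len(c.positions) >= config.region_n_cpgs]
    subtypes = APL_SUBTYPES
    need = (
        len(subtypes)
        * (config.planted_regions_per_subtype + config.signature_regions_per_subtype)
        + config.n_promoter_clusters
    )
    if need > len(eligible):
        raise ValueError(
            f"infeasible geometry: need {need} cluster(s) of >= "
            f"{config.region_n_cpgs} CpGs but only {len(eligible)} exist"
        )
    chosen = rng_assign.choice(len(eligible), size=need, replace=False)
    chosen_iter = iter(int(eligible[i]) for i in chosen)

    # cohort-level site means
    rng_base = _substream(config.seed, 3)
    m = rng_base.beta(config.background_beta_alpha, config.background_beta_beta, size=n_sites)
    delta = config.planted_delta
    hyper_hi = max(0.06, 1.0 - delta - 0.1)
    hypo_lo = min(0.94, delta + 0.1)

    truth = SyntheticTruth()
    shift_tumor = {s.value: np.zeros(n_sites) for s in subtypes}  # tumor-only shift
    shift_both = {s.value: np.zeros(n_sites) for s in subtypes}  # both-tissue shift

    n_hyper = round(config.planted_regions_per_subtype * config.hyper_fraction)
    for s in subtypes:
        for j in range(config.planted_regions_per_subtype):
            c = clusters[next(chosen_iter)]
            direction = "hyper" if j < n_hyper else "hypo"
            if direction == "hyper":
                m[c.index] = rng_base.uniform(0.05, hyper_hi, size=len(c.positions))
                shift_tumor[s.value][c.index] = delta
            else:
                m[c.index] = rng_base.uniform(hypo_lo, 0.94, size=len(c.positions))
                shift_tumor[s.value][c.index] = -delta
            truth.regions.append(
                PlantedRegion(*c.span, s.value, direction, delta, KIND_TUMOR_VS_NAT)
            )
        for _ in range(config.signature_regions_per_subtype):
            c = clusters[next(chosen_iter)]
            m[c.index] = rng_base.uniform(0.05, hyper_hi, size=len(c.positions))
            shift_both[s.value][c.index] = delta
            truth.regions.append(
                PlantedRegion(*c.span, s.value, "hyper", delta, KIND_SIGNATURE)
            )

    panel_mask = np.zeros(n_sites, dtype=bool)
    for _ in range(config.n_promoter_clusters):
        c = clusters[next(chosen_iter)]
        m[c.index] = rng_base.uniform(0.005, 0.03, size=len(c.positions))
        panel_mask[c.index] = True
        chrom, start, end = c.span
        truth.promoters.append((chrom, max(1, start - 20), end + 20))
    chroms_idx = index.get_level_values("chrom")
    poss_idx = index.get_level_values("pos")
    truth.panel_sites = [
        (str(c), int(p)) for c, p in zip(chroms_idx[panel_mask], poss_idx[panel_mask])
    ]

    # samples
    records: list[SampleRecord] = []
    meth_cols: dict[str, np.ndarray] = {}
    unmeth_cols: dict[str, np.ndarray] = {}
    kappa = config.patient_concentration
    m_clipped = np.clip(m, 1e-3, 1.0 - 1e-3)
    for si, s in enumerate(subtypes):
        for pi in range(config.n_patients_per_subtype):
            patient = f"{s.value}_P{pi:02d}"
            rng_pat = _substream(config.seed, 4, si, pi)
            m_pat = np.clip(m_clipped + shift_both[s.value], 1e-3, 1.0 - 1e-3)
            p0 = rng_pat.beta(m_pat * kappa, (1.0 - m_pat) * kappa)
            is_cimp = bool(rng_pat.random() < config.cimp_fraction)
            for tissue in (Tissue.tumor, Tissue.NAT):
                sid = f"{s.value}_{pi:02d}_{'T' if tissue == Tissue.tumor else 'N'}"
                records.append(SampleRecord(sid, patient, tissue, s, Split.discovery))
                p = p0.copy()
                if tissue == Tissue.tumor:
                    p = p + shift_tumor[s.value]
                    if is_cimp:
                        p[panel_mask] += config.cimp_delta
                    truth.cimp_labels[sid] = "CIMP-H" if is_cimp else "CIMP-L/N"
                p = np.clip(p, 0.0, 1.0)
                rng_cnt = _substream(config.seed, 5, si, pi, int(tissue == Tissue.tumor))
                depth = rng_cnt.poisson(config.mean_depth, size=n_sites)
                mc = rng_cnt.binomial(depth, p)
                meth_cols[sid] = mc.astype(np.int64)
                unmeth_cols[sid] = (depth - mc).astype(np.int64)

    sites = CpGSiteTable(
        pd.DataFrame(meth_cols, index=index),
        pd.DataFrame(unmeth_cols, index=index),
    )
    samples = SampleSheet(records)
    genome = GenomeInfo({f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)})
    cohort = SyntheticCohort(sites=sites, samples=samples, truth=truth, genome=genome)
    if out_dir is not None:
        cohort.files = _emit(cohort, Path(out_dir))
    return cohort


def generate_null_cohort(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SyntheticCohort:
    """A cohort with nothing planted: no regions, no CIMP-H samples."""
    null_cfg = SimulationConfig(
        **{
            **asdict(config),
            "planted_regions_per_subtype": 0,
            "signature_regions_per_subtype": 0,
            "cimp_fraction": 0.0,
            "n_promoter_clusters": 0,
        }
    )
    return generate_cohort(null_cfg, out_dir=out_dir)


def _emit(cohort: SyntheticCohort, out_dir: Path) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    index = cohort.sites.index
    base = pd.DataFrame(
        {
            "chrom": index.get_level_values("chrom"),
            "pos": index.get_level_values("pos"),
        }
    )
    for sid in cohort.sites.samples:
        df = base.copy()
        df["meth"] = cohort.sites.meth[sid].to_numpy()
        df["unmeth"] = cohort.sites.unmeth[sid].to_numpy()
        path = out_dir / f"{sid}.cov"
        write_bismark_cov(df, path)
        files[f"cov:{sid}"] = path
    files["sample_sheet"] = out_dir / "sample_sheet.tsv"
    write_sample_sheet(cohort.samples, files["sample_sheet"])
    files["truth"] = out_dir / "truth.json"
    cohort.truth.to_json(files["truth"])
    files["chrom_sizes"] = out_dir / "chrom.sizes"
    write_chrom_sizes(cohort.genome, files["chrom_sizes"])
    if cohort.truth.promoters:
        files["promoters"] = out_dir / "promoters.bed"
        write_bed_intervals(cohort.truth.promoters, files["promoters"])
    return files
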