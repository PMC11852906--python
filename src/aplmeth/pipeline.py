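"""End-to-end workflow wiring: simulate -> filter -> test -> DMR -> signature
-> stratification -> CIMP, with a reproducibility manifest.

Two layers: :func:`analyze_cohort` runs the whole analysis in memory on a
count table + sample sheet (the API the tests and acceptance checks use);
:func:`run_pipeline` wraps it with file I/O, per-stage logging and a JSON
manifest so a run can be reproduced bit-exactly from its config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .cimp import CIMPConfig, CIMPResult, classify_cimp
from .io import (
    APL_SUBTYPES,
    CpGSiteTable,
    GenomeInfo,
    SampleSheet,
    Subtype,
    Tissue,
    read_chrom_sizes,
    read_cov_files,
    read_sample_sheet,
    read_bed_intervals,
    write_dmr_bed,
)
from .regions import DMR, ComparisonSummary, call_dmrs, summarize_comparisons
from .signature import (
    SignatureSet,
    chromosome_enrichment,
    region_beta_matrix,
    select_unique_hyper,
)
from .simulate import SimulationConfig, generate_cohort
from .sites import AnalysisConfig, filter_sites, test_sites, write_site_results
from .stratify import KWResult, PCAResult, kruskal_subtypes, pca_stratify

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class Comparison:
    label: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    paired: bool
    kind: str  # "vs_nat" | "inter" | "nat_nat"


def standard_comparisons(samples: SampleSheet) -> list[Comparison]:
    """The nine-comparison design: each subtype vs its own NATs (paired),
    tumors across subtypes, and NATs across subtypes (both unpaired).

    Subtypes with fewer than 3 paired patients are left out.
    """
    present = [
        s for s in APL_SUBTYPES if len(samples.pairs(subtype=s)) >= 3
    ]
    out: list[Comparison] = []
    for s in present:
        pairs = samples.pairs(subtype=s)
        out.append(
            Comparison(
                label=f"{s.value}_vs_{s.value}_NAT",
                group_a=tuple(t for t, _ in pairs),
                group_b=tuple(n for _, n in pairs),
                paired=True,
                kind="vs_nat",
            )
        )
    for i, a in enumerate(present):
        for b in present[i + 1 :]:
            out.append(
                Comparison(
                    label=f"{a.value}_vs_{b.value}",
                    group_a=tuple(samples.samples(tissue=Tissue.tumor, subtype=a)),
                    group_b=tuple(samples.samples(tissue=Tissue.tumor, subtype=b)),
                    paired=False,
                    kind="inter",
                )
            )
    for i, a in enumerate(present):
        for b in present[i + 1 :]:
            out.append(
                Comparison(
                    label=f"{a.value}_NAT_vs_{b.value}_NAT",
                    group_a=tuple(samples.samples(tissue=Tissue.NAT, subtype=a)),
                    group_b=tuple(samples.samples(tissue=Tissue.NAT, subtype=b)),
                    paired=False,
                    kind="nat_nat",
                )
            )
    return out


@dataclass
class CohortAnalysis:
    """In-memory results of the full analysis on one cohort."""

    filtered: CpGSiteTable
    site_results: dict[str, pd.DataFrame]
    dmrs: dict[str, list[DMR]]
    summary: ComparisonSummary
    comparisons: list[Comparison]
    signature: SignatureSet | None = None
    enrichment: pd.DataFrame | None = None
    pca: PCAResult | None = None
    kw: KWResult | None = None
    cimp: CIMPResult | None = None


def analyze_cohort(
    sites: CpGSiteTable,
    samples: SampleSheet,
    config: AnalysisConfig | None = None,
    cimp_config: CIMPConfig | None = None,
    genome: GenomeInfo | None = None,
    promoters: Sequence[tuple[str, int, int]] | None = None,
    comparisons: Sequence[Comparison] | None = None,
) -> CohortAnalysis:
    """Run filter -> test -> DMR -> signature -> PCA/KW -> CIMP in memory.

    Signature/stratification/CIMP stages are skipped (left None) when their
    inputs are legitimately empty — e.g. no signature regions on a null
    cohort, or no promoter set supplied.
    """
    config = config or AnalysisConfig()
    if comparisons is None:
        comparisons = standard_comparisons(samples)
    filtered = filter_sites(sites, config, samples.sample_ids)

    site_results: dict[str, pd.DataFrame] = {}
    dmrs: dict[str, list[DMR]] = {}
    for comp in comparisons:
        res = test_sites(filtered, comp.group_a, comp.group_b, comp.paired, config)
        site_results[comp.label] = res
        dmrs[comp.label] = call_dmrs(res, config, comp.label)
        log.info(
            "comparison %s: %d significant sites, %d DMRs",
            comp.label,
            int(res["significant"].sum()),
            len(dmrs[comp.label]),
        )
    summary = summarize_comparisons(dmrs)

    analysis = CohortAnalysis(
        filtered=filtered,
        site_results=site_results,
        dmrs=dmrs,
        summary=summary,
        comparisons=list(comparisons),
    )

    inter = {c.label: dmrs[c.label] for c in comparisons if c.kind == "inter"}
    vs_nat = {c.label: dmrs[c.label] for c in comparisons if c.kind == "vs_nat"}
    if inter:
        analysis.signature = select_unique_hyper(inter, vs_nat)
    if genome is not None:
        all_dmrs = [d for ds in dmrs.values() for d in ds]
        analysis.enrichment = chromosome_enrichment(all_dmrs, genome)

    if analysis.signature is not None and len(analysis.signature.regions) >= 2:
        tumors = samples.samples(tissue=Tissue.tumor)
        matrix = region_beta_matrix(analysis.signature.regions, filtered, tumors)
        analysis.pca = pca_stratify(matrix)
        subtype_of = {
            r.sample_id: r.subtype.value for r in samples if r.tissue == Tissue.tumor
        }
        pc1 = analysis.pca.scores["PC1"]
        labels = [subtype_of[s] for s in pc1.index]
        if len(set(labels)) >= 2:
            analysis.kw = kruskal_subtypes(pc1.to_numpy(), labels)

    if cimp_config is not None and (
        promoters is not None or cimp_config.promoter_regions is not None
    ):
        try:
            analysis.cimp = classify_cimp(filtered, samples, cimp_config, promoters)
        except ValueError as exc:
            log.warning("CIMP stage skipped: %s", exc)
    return analysis


# ---------------------------------------------------------------------------
# File-based orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    version: str
    seed: int | None
    config: dict
    input_digests: dict[str, str]
    stages: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=str))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: pipeline config must be a mapping")
    return cfg


def run_pipeline(config: str | Path | Mapping, out_dir: str | Path) -> RunManifest:
    """Execute the full workflow from a flat YAML config.

    Config blocks: ``seed``; ``simulate`` (SimulationConfig fields) OR
    ``inputs`` (cov_dir, sample_sheet, chrom_sizes, promoters); ``analysis``
    (AnalysisConfig fields); ``cimp`` (CIMPConfig fields). Outputs land under
    ``out_dir`` with a ``manifest.json`` capturing config, input digests and
    per-stage record counts.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.get("seed")
    manifest = RunManifest(
        version=__version__, seed=seed, config=cfg, input_digests={}
    )

    promoters = None
    genome = None
    if "simulate" in cfg:
        stage = "simulate"
        try:
            sim_cfg = SimulationConfig(**{**cfg["simulate"], **({"seed": seed} if seed is not None else {})})
            cohort = generate_cohort(sim_cfg, out_dir=out / "cohort")
            sites, samples = cohort.sites, cohort.samples
            genome = cohort.genome
            promoters = cohort.truth.promoters or None
            manifest.stages[stage] = {
                "n_sites": sites.n_sites,
                "n_samples": len(samples),
                "out": str(out / "cohort"),
            }
        except Exception as exc:
            raise StageError(stage, exc) from exc
    else:
        stage = "load"
        try:
            inputs = cfg["inputs"]
            sheet_path = Path(inputs["sample_sheet"])
            samples = read_sample_sheet(sheet_path)
            cov_dir = Path(inputs["cov_dir"])
            paths = {sid: cov_dir / f"{sid}.cov" for sid in samples.sample_ids}
            for p in paths.values():
                if not p.exists():
                    raise FileNotFoundError(f"missing coverage file {p}")
            sites = read_cov_files(paths)
            manifest.input_digests[str(sheet_path)] = _sha256(sheet_path)
            for p in paths.values():
                manifest.input_digests[str(p)] = _sha256(p)
            if "chrom_sizes" in inputs:
                genome = read_chrom_sizes(inputs["chrom_sizes"])
            if "promoters" in inputs:
                promoters = read_bed_intervals(inputs["promoters"])
            manifest.stages[stage] = {
                "n_sites": sites.n_sites,
                "n_samples": len(samples),
            }
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, exc) from exc

    try:
        config_a = AnalysisConfig(**cfg.get("analysis", {}))
        cimp_cfg = CIMPConfig(**{"seed": seed or 0, **cfg.get("cimp", {})})
        analysis = analyze_cohort(
            sites,
            samples,
            config=config_a,
            cimp_config=cimp_cfg,
            genome=genome,
            promoters=promoters,
        )
    except Exception as exc:
        raise StageError("analysis", exc) from exc

    try:
        dmr_dir = out / "dmrs"
        dmr_dir.mkdir(exist_ok=True)
        for label, res in analysis.site_results.items():
            write_site_results(res, dmr_dir / f"{label}.sites.tsv")
            write_dmr_bed(analysis.dmrs[label], dmr_dir / f"{label}.dmrs.bed")
        analysis.summary.to_frame().to_csv(out / "summary.tsv", sep="\t", index=False)
        manifest.stages["dmr"] = {
            label: len(d) for label, d in analysis.dmrs.items()
        }
        if analysis.signature is not None:
            analysis.signature.to_frame().to_csv(
                out / "signature.tsv", sep="\t", index=False
            )
            manifest.stages["signature"] = {
                "n_regions": len(analysis.signature.regions),
                "n_candidates": analysis.signature.n_candidates,
                "n_nat_excluded": analysis.signature.n_nat_excluded,
                "n_ambiguous": analysis.signature.n_ambiguous,
            }
        if analysis.enrichment is not None:
            analysis.enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        if analysis.pca is not None:
            analysis.pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
            analysis.pca.loadings.to_csv(out / "pca_loadings.tsv", sep="\t")
            analysis.pca.top_regions(30).to_csv(
                out / "pca_top_regions.tsv", sep="\t", index=False
            )
            manifest.stages["stratify"] = {
                "n_components": len(analysis.pca.components),
                "kw_p_global": analysis.kw.p_global if analysis.kw else None,
            }
        if analysis.cimp is not None:
            pd.Series(analysis.cimp.labels, name="cimp").rename_axis(
                "sample_id"
            ).to_csv(out / "cimp.tsv", sep="\t")
            manifest.stages["cimp"] = {
                "n_cimp_high": sum(
                    1 for v in analysis.cimp.labels.values() if v == "CIMP-H"
                ),
                "n_selected_cpgs": len(analysis.cimp.selected_cpgs),
            }
    except Exception as exc:
        raise StageError("write", exc) from exc

    manifest.to_json(out / "manifest.json")
    return manifest
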