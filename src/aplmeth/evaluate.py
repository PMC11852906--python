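"""Recovery metrics of an analysis against a synthetic cohort's ground truth.

Used to quantify, on simulated cohorts, how well the pipeline recovers what
was planted: lesion-vs-NAT region recovery, signature subtype assignment,
false-region calls outside planted territory, and CIMP label accuracy.
Overlap is >= 1 bp throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._intervals import build_interval_index, overlaps_any
from .pipeline import CohortAnalysis
from .simulate import KIND_SIGNATURE, KIND_TUMOR_VS_NAT, SyntheticTruth


@dataclass
class RecoveryReport:
    n_planted: int
    n_recovered: int

    @property
    def rate(self) -> float:
        return self.n_recovered / self.n_planted if self.n_planted else float("nan")


def vs_nat_recovery(analysis: CohortAnalysis, truth: SyntheticTruth) -> RecoveryReport:
    """Planted tumor-vs-NAT regions recovered, with matching direction, in
    their own subtype's lesion-vs-NAT comparison."""
    n_planted = 0
    n_recovered = 0
    by_comp: dict[str, dict[str, dict]] = {}
    for comp in analysis.comparisons:
        if comp.kind != "vs_nat":
            continue
        subtype = comp.label.split("_vs_")[0]
        dmrs = analysis.dmrs[comp.label]
        by_comp[subtype] = {
            "hyper": build_interval_index(d.interval for d in dmrs if d.direction == "hyper"),
            "hypo": build_interval_index(d.interval for d in dmrs if d.direction == "hypo"),
        }
    for r in truth.regions_of(KIND_TUMOR_VS_NAT):
        if r.subtype not in by_comp:
            continue
        n_planted += 1
        idx = by_comp[r.subtype][r.direction]
        if overlaps_any(r.chrom, r.start, r.end, idx):
            n_recovered += 1
    return RecoveryReport(n_planted, n_recovered)


def signature_assignment(analysis: CohortAnalysis, truth: SyntheticTruth) -> RecoveryReport:
    """Planted subtype-signature regions present in the signature set AND
    assigned to the planted subtype."""
    if analysis.signature is None:
        return RecoveryReport(len(truth.regions_of(KIND_SIGNATURE)), 0)
    by_subtype = {
        s: build_interval_index(r.interval for r in analysis.signature.by_subtype(s))
        for s in analysis.signature.subtypes
    }
    wrong = build_interval_index([])
    n_planted = 0
    n_correct = 0
    for r in truth.regions_of(KIND_SIGNATURE):
        n_planted += 1
        hit_own = overlaps_any(r.chrom, r.start, r.end, by_subtype.get(r.subtype, {}))
        hit_other = any(
            overlaps_any(r.chrom, r.start, r.end, idx)
            for s, idx in by_subtype.items()
            if s != r.subtype
        )
        if hit_own and not hit_other:
            n_correct += 1
    return RecoveryReport(n_planted, n_correct)


def signature_leakage(analysis: CohortAnalysis, truth: SyntheticTruth) -> int:
    """Signature regions overlapping planted tumor-vs-NAT territory — regions
    that should have been removed by the vs-NAT overlap exclusion."""
    if analysis.signature is None:
        return 0
    planted = build_interval_index(
        r.interval for r in truth.regions_of(KIND_TUMOR_VS_NAT)
    )
    return sum(
        overlaps_any(r.chrom, r.start, r.end, planted) for r in analysis.signature.regions
    )


def false_region_calls(
    analysis: CohortAnalysis, truth: SyntheticTruth, pad: int = 1000
) -> int:
    """DMR calls farther than ``pad`` bp from any planted perturbation.

    Planted territory includes all planted regions plus the CIMP promoter
    panel (whose tumors are genuinely perturbed in CIMP-H patients).
    """
    planted = build_interval_index(
        [(r.chrom, max(1, r.start - pad), r.end + pad) for r in truth.regions]
        + [(c, max(1, s - pad), e + pad) for c, s, e in truth.promoters]
    )
    return sum(
        not overlaps_any(d.chrom, d.start, d.end, planted)
        for dmrs in analysis.dmrs.values()
        for d in dmrs
    )


def cimp_accuracy(analysis: CohortAnalysis, truth: SyntheticTruth) -> float:
    """Fraction of tumors whose CIMP call matches the planted label."""
    if analysis.cimp is None or not truth.cimp_labels:
        return float("nan")
    hits = [
        analysis.cimp.labels.get(s) == label for s, label in truth.cimp_labels.items()
    ]
    return float(np.mean(hits))
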