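"""Generate a synthetic paired tumor/NAT cohort and inspect its structure.

The generator plants three kinds of ground truth: tumor-vs-NAT shifted
regions (per subtype, hyper or hypo), subtype-signature regions elevated in
both tissues of one subtype's patients, and a promoter panel hypermethylated
in CIMP-H tumors.
"""

from aplmeth import SimulationConfig, Tissue, generate_cohort
from aplmeth.simulate import KIND_SIGNATURE, KIND_TUMOR_VS_NAT

cohort = generate_cohort(SimulationConfig(seed=1))

print(f"CpG sites:        {cohort.sites.n_sites}")
print(f"samples:          {len(cohort.samples.records)} "
      f"({len(cohort.samples.pairs())} tumor/NAT pairs)")
print(f"mean depth:       {cohort.sites.depth().to_numpy().mean():.1f}x")
tv = cohort.truth.regions_of(KIND_TUMOR_VS_NAT)
sig = cohort.truth.regions_of(KIND_SIGNATURE)
print(f"planted regions:  {len(tv)} tumor-vs-NAT, {len(sig)} subtype-signature")
n_cimp = sum(1 for v in cohort.truth.cimp_labels.values() if v == "CIMP-H")
n_tumors = len(cohort.samples.samples(tissue=Tissue.tumor))
print(f"CIMP-H tumors:    {n_cimp} of {n_tumors}")
print(f"promoter panel:   {len(cohort.truth.promoters)} clusters, "
      f"{len(cohort.truth.panel_sites)} CpGs")
# Each pair shares a patient baseline, so tumor and NAT betas are correlated;
# read counts are Poisson-depth binomial draws from the per-tissue
# methylation probabilities.
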