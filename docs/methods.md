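# Methods

This note records the statistical model, the defaults and why they are what
they are, what the synthetic cohorts do and do not emulate, and the design
choices made where the design was genuinely open.

## Site-level testing

Betas are recomputed from read counts (β = M/(M+U); missing iff depth 0);
the percentage column of coverage reports is ignored to avoid rounding
drift. The coverage filter requires ≥ `min_coverage` (default 5) reads in
*every* analysis sample, applied once over the whole cohort before any
comparison. An optional BED mask removes CpGs at common variants; the caller
is expected to pre-compute which SNPs exceed the MAF threshold — the package
treats the mask as given.

Lesion vs matched NAT uses the paired Wilcoxon signed-rank on per-patient
beta differences; comparisons across subtypes involve disjoint patients, so
the unpaired rank-sum test is used there — the only reading of a "paired"
design consistent with the cohort structure. Both tests run vectorized over
all sites (`ranktests.py`):

* zero differences are dropped before ranking (Wilcoxon's original
  convention, the common library default, rather than Pratt's);
* exact null distributions (generating-polynomial recursion for W⁺, the
  standard partition recurrence for U) are used when the ranked magnitudes
  are tie-free and the group size is ≤ 25; otherwise a tie-corrected normal
  approximation with continuity correction. The policy and the two-sided
  definition `min(1, 2·min(P(T≤t), P(T≥t)))` match scipy's scalar routines,
  which the test suite uses as an independent reference alongside
  brute-force enumeration;
* sites with < 3 informative pairs get p = 1 and an `untestable` flag; they
  are reported, never dropped, so region CpG counts stay aligned with the
  filtered table.

BH adjustment is applied per comparison across all tested CpGs jointly (one
adjustment per pairwise analysis, not per chromosome), delegated to
statsmodels' step-up implementation. Significance: p_adj < α (0.05) AND
|Δβ| ≥ 0.2, with Δβ = mean(A) − mean(B) and "hyper" meaning the first-named
group is higher.

## DMR aggregation

Clustering runs over *all* tested CpGs — significance enters only through
the within-run fraction, since a "≥ 60% significant" rule presupposes
regions containing non-significant CpGs. Successive CpGs join a run when
their coordinate difference is ≤ 50 bp (51 splits); runs need ≥ 3 CpGs and a
significant fraction ≥ 0.6, inclusive at the boundary (3 of 5 qualifies).
Significant CpGs in a retained run must share one sign of Δβ; mixed-sign
runs are discarded rather than split (regions are labelled hyper or hypo as
wholes; a splitting policy would be arbitrary). Region coordinates span the
first to last CpG with no flanking padding. Comparison summaries count every
row into the grand total; hyper/hypo totals cover only rows with direction
assigned (NAT-vs-NAT rows may be reported without direction).

## Signature selection

Candidates are all DMRs from the inter-subtype comparisons, each assigned
to its *elevated* side (Δβ > 0 → first-named subtype, Δβ < 0 → second).
Assigning only `direction == hyper` DMRs would make the last-named subtype
structurally signature-less under the canonical comparison orientations, so
elevated-side assignment is used; hypomethylation artifacts that would be
mis-claimed by the unaffected side of a comparison are precisely the regions
the next step removes. Candidates overlapping any lesion-vs-NAT DMR by
≥ 1 bp are excluded; mutually overlapping survivors claimed by a single
subtype merge into one region (union interval, provenance kept), groups
claimed by two subtypes are dropped as ambiguous. The 1 bp-intersection
predicate is the least restrictive standard choice. The exclusion operates
on *called* vs-NAT DMRs: a lesion-vs-NAT effect the caller misses cannot be
excluded, so on noisy data a small number of tumor-only regions can survive
into the signature (~1% of plants at the default conditions).

Chromosome enrichment is (n_c/L_c)/(N/L) over autosomes only; by
construction the length-weighted mean is exactly 1, and values > 1.5 are
flagged. The region-beta matrix takes the unweighted mean beta of a
region's CpGs per sample, missing when a sample has no covered CpG there.

## Stratification

PCA treats samples as observations and signature regions as features:
region-mean imputation of missing entries, centering, unit scaling
(zero-variance regions dropped with a warning — beta variances differ
strongly across regions, and scaling stabilizes the stratification), full
SVD. Components are oriented so the largest-|loading| region loads
positively, making scores deterministic and sample-order invariant. The
Kruskal–Wallis test runs on PC1 *sample scores* grouped by subtype — the
only reading of "contributions of the first component" that yields
per-sample groups — with tie-corrected H referred to χ²(k−1); pairwise
rank-sum p-values are reported unadjusted. Region contribution percentages
(squared-loading shares) are computed separately for the top-k report.
Validation samples can either be co-decomposed (default) or projected onto
discovery components via `project_samples`.

## CIMP classification

Candidate CpGs: inside the promoter BED, tumor-beta SD > 0.2 (ddof = 1,
matching R's `sd`) and normal mean β < 0.05. Consensus clustering runs
`n_resamples` = 100 rounds, each subsampling 80% of samples *and* items
(item subsampling alongside sample subsampling is common consensus-
clustering practice), K-means with k = 2 (the cohort-scale dichotomy
CIMP-H vs CIMP-L/N) seeded from the round's substream. consensus(i,j) =
co-cluster/co-sampled counts; never co-sampled pairs are mean-imputed with
a warning. The final partition is an average-linkage cut of 1 − consensus;
the higher-mean-beta cluster is CIMP-H. Everything is reproducible from one
seed; with `subsample_frac = 1` and deterministic initialization the
consensus matrix is exactly binary. The resample count, linkage and k are
documented defaults, not values inherited from any particular study.

## Synthetic cohorts

The generator emulates the data structure the analysis assumes: three APL
subtypes, one tumor and one NAT per patient, clustered CpG placement (3–8
CpGs per cluster, 10–40 bp intra-cluster gaps, 300–1500 bp between
clusters), hierarchical methylation — cohort site mean m ~ Beta(0.4, 0.4)
(bimodal, as methylomes are), patient baseline p₀ ~ Beta(mκ, (1−m)κ) with
κ = 60 shared by both tissues of a patient (this sharing is what the paired
test exploits), depth ~ Poisson(22.5), meth ~ Binomial(depth, p). Poisson
depth (not negative binomial) keeps the model minimal; over-dispersion
would be a config extension. One seed feeds keyed substreams per patient
and per sample, so adding patients never perturbs existing draws.

Planted truth, all in whole clusters of ≥ 5 CpGs:

* **tumor-vs-NAT regions** (120 per subtype, half hyper/half hypo,
  |Δβ| = 0.35): tumor-only shifts in one subtype. Cluster baselines are
  drawn with headroom (hyper: m ∈ [0.05, 1−Δ−0.1]; hypo mirrored) so the
  realized shift is unclipped and the empirical Δβ matches the nominal one.
* **subtype-signature regions** (40 per subtype, hyper): the site mean
  shifts in *both* tissues of one subtype's patients — a field-effect-style
  change that surfaces only in inter-subtype (and NAT-vs-NAT) comparisons
  and therefore survives the signature's vs-NAT exclusion. Tumor-only
  shifts cannot populate the signature by construction of the exclusion
  rule, so subtype signatures are modelled this way.
* **promoter panel** (30 clusters, baseline β ≈ 0.005–0.03): tumors of
  CIMP-H patients (fraction 0.4) gain Δβ = 0.5 there. 0.5 rather than a
  smaller shift keeps the tumor-SD selection rule (SD > 0.2) away from its
  knife edge: the between-class SD at fraction f is Δ·√(f(1−f)) ≈ 0.245.

Default sizes are a power calculation, not a convenience: with 10 pairs the
exact two-sided signed-rank floor is 2/2¹⁰ ≈ 0.00195, so BH significance
requires the threshold 0.05·m/n to exceed that floor — about m/n ≥ 1/25
true sites. 120 regions × 5 CpGs = 600 planted sites per lesion-vs-NAT
comparison against 10,000 tested CpGs gives a threshold ≈ 2.8×10⁻³ with a
comfortable margin; fewer plants, more CpGs, or fewer pairs would make the
paired arm unpowerable regardless of implementation. Null cohorts for
false-region control use 50,000 CpGs (nothing planted, so no m/n
constraint). Unpaired inter-subtype tests (10 vs 10; exact floor ≈ 10⁻⁵)
are far less constrained.

What the generator does *not* emulate: strand, sequence context and CpG
islands as such; read-level artifacts (bisulfite conversion failure,
mapping bias); depth over-dispersion; covariates (age, sex, batch);
copy-number or mutational co-variation; and any NAT-vs-NAT noise structure
beyond the planted field effects — NATs of different subtypes are otherwise
exchangeable. Passing tests therefore demonstrate the correctness of the
statistics and the set algebra under the stated generative model, not
performance on real tissue.

## Numerical notes and degenerate inputs

* Exact p-value lookups are grouped by effective sample size; tie detection
  uses exact float equality of ranked magnitudes (betas are ratios of small
  integers, so ties are real, not numerical noise).
* BH on an empty vector returns an empty vector; an empty DMR list writes a
  header-only BED; an all-filtered site table warns rather than errors.
* `pca_stratify` needs ≥ 3 samples and ≥ 2 informative regions; K-means
  consensus needs ≥ k+1 samples; tied CIMP cluster means label everything
  CIMP-L/N with a warning.
* Internally all coordinates are 1-based inclusive (the coverage-report
  convention); BED export converts to 0-based half-open. CpGs are keyed by
  (chrom, pos) only — strand handling, and any merging of symmetric CpG
  pairs, is upstream's responsibility.

## Problem sizes used in the checks

The bundled acceptance checks run 20 planted cohorts (10,000 CpGs, 30
pairs) and 20 null cohorts (50,000 CpGs, 30 pairs); the statistical-oracle
checks enumerate all group sizes up to 8. These sizes were chosen as the
smallest at which the power analysis above holds with margin.
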