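# Methods

This note documents the models behind each `tetrapop` stage, the
parameters that matter, the numerical choices, and what the synthetic
benchmark does and does not establish about real data.

## The synthetic landscape generator

The generator is the package's measurement instrument: every accuracy
claim in the test suite is scored against its recorded truth.

**Landscape.** Localities are placed uniformly at random on a local
tangent plane (a square of side `extent_km`, default 500 km) centred on
a fixed Mediterranean origin and converted to latitude/longitude. All
distances everywhere in the package are haversine great-circle
distances (Earth radius 6,371.0088 km) — one convention throughout.
Each climatic covariate is a linear north–south gradient in z-scored
latitude plus independent Gaussian noise (`noise_sd`, default 0.3), so
covariates are spatially autocorrelated the way real bioclimatic
surfaces are. Defaults: 16 localities, 9 individuals each, 3
covariates named after the precipitation bioclim layers.

**Allele frequencies.** Per locus, an ancestral frequency
p₀ ~ Uniform(0.05, 0.95) and population frequencies

  p_j = logit⁻¹( logit p₀ + e_j ),  Cov(e_j, e_k) = σ² exp(−d_jk / λ)

with σ = `base_sd` (default 0.5) and λ = `ibd_range` (default 200 km),
clamped to [0.001, 0.999]. This is the simplest model producing both
isolation by distance and, by adding `effect_size` × (z-scored
covariate) to the logit at flagged loci, tunable isolation by
environment. It is **not** a coalescent: loci are independent (as RAD
tags effectively are), there is no linkage, and drift is not
Wright–Fisher-scaled — see the calibration caveat below. The uniform
ancestral spectrum is a stand-in (real RAD MAF spectra are strongly
L-shaped) and is deliberately conservative for genotype-calling
benchmarks, since intermediate frequencies maximise heterozygote
ambiguity.

**Genotypes.** Tetrasomic mode draws dosage ~ Binomial(4, p) —
free pairing of all four homologues. Disomic mode draws
Binomial(2, p+δ/2) + Binomial(2, p−δ/2) (clamped), two subgenomes
separated by δ = `subgenome_divergence`; δ = 0 reduces exactly to the
tetrasomic distribution and δ = 1 at p = 0.5 gives fixed duplex
heterozygosity, the allopolyploid extreme.

**Reads.** Depth is negative-binomial via a gamma–Poisson mixture with
mean 16 and dispersion 12.8, chosen so the SD is exactly 6 — a typical
medium-coverage RAD regime. Each read is independently recorded as a
third allele with probability ε/2 (`error_rate`/2, default
0.005/2) and otherwise reports the alternative allele with probability
g/4, flipped with probability ε/2. Splitting the error evenly between
third-allele reads and cross-allele flips gives the error estimator
real signal while keeping the flip component that actually corrupts
dosage likelihoods.

One global seed fans out to per-stage seeds by a fixed counter scheme,
so identical seeds give bit-identical datasets and toggling one stage
never perturbs another's draws.

## Genotype calling

Per site, the error rate is estimated as ε̂ = (1 + Σother)/(2 + Σdepth)
— a pseudocount-stabilised fraction of reads matching neither allele —
clamped to [10⁻⁴, 0.1] to keep likelihoods proper. The dosage
likelihood is Binomial(a; d, h_g) with h_g = (g/4)(1−ε) + (1−g/4)ε,
where d counts reads matching **either** allele: conditioning out the
third-allele reads makes the model exactly symmetric under ref/alt
relabelling (dosage g ↦ 4−g, verified exactly in the tests).

The site allele frequency q is fitted by EM under the tetrasomic
Hardy–Weinberg prior Binomial(g; 4, q) (E-step posterior ∝ likelihood ×
prior; M-step q = Σ E[g]/4n; tolerance 10⁻⁶, cap 100 iterations; the
observed-data log-likelihood is non-decreasing, tested). The HWE prior
is justified by the near-zero F_IS this class of data shows; posterior
dosage is the argmax, with ties broken deterministically toward the
dosage nearest 4q̂.

Cells below depth 5 are missing. Sites are dropped when more than 10%
of individuals are missing, the minor allele frequency is below
`maf_min` (default 0.05 — conventional for structure analyses at this
sample size; no canonical value exists) or fewer than 2 called
individuals carry either allele. The carrier filter is this package's
stand-in for an upstream site-quality score: it removes the same class
of singleton-noise sites without requiring per-read qualities.

**Accuracy.** At 16× mean depth with the broad frequency spectrum
above, called dosages match truth for ~86% of cells. This is the
information limit, not a deficiency: a Bayes-optimal oracle given the
*true* per-cell frequency prior reaches ~86.5% (the acceptance suite
recomputes both), because at depth ~16 the three heterozygote
likelihoods overlap heavily. Concordance exceeds 95% by ~50× depth
(tested), and homozygotes are nearly always correct at 16×. Real
datasets with L-shaped MAF spectra sit well above the synthetic figure.

## Inheritance diagnosis

Complete-case sites are binned by allele frequency (bin width 0.02) and
their dosage-class proportions averaged per bin. Within the
intermediate band (default q ∈ [0.4, 0.6]) the observed class
distribution is compared by total-variation distance to (i) the
tetrasomic expectation Binomial(4, q) per bin and (ii) a
fixed-difference disomic reference (one subgenome fixed: dosage ~
Binomial(2, 2q) for q ≤ 0.5, mirrored above, a point mass on duplex at
q = 0.5). The nearer model wins; a margin of 0.05 yields "ambiguous",
sized so that weakly diverged allotetraploids (δ ≈ 0.4) land in
"ambiguous" rather than being mislabelled. The extreme reference is
intentional: intermediate allopolyploids genuinely cannot be resolved
from dosage spectra alone, and the classifier says so rather than
guessing. The heterozygote balance D = (f₁+f₃)/f₂ is reported without
interpretation; its HWE value is 4/3, but drift and structure move it
upward in real data.

## Diversity and differentiation

Gene diversity uses the unbiased polysomic estimator
Hs = (m/(m−1))·2q(1−q) over m = 4·n_called allele copies; He averages
Hs over all retained SNPs (within-locality monomorphic SNPs contribute
0). π divides ΣHs by the callable bases, default 94 bp per SNP locus
(the RAD-tag length; exposed as a parameter, since the right
denominator depends on how loci were assembled) — which is why π is an
order of magnitude below He. Ho is the within-individual
heterozygosity g(4−g)/6 (heterozygous pairs among the six copy-pairs);
F_IS = 1 − Ho/He.

Pairwise F_ST is a ratio of sums over sites:
F_ST = Σ(H_T − H_S)/ΣH_T, with H_S the mean of the two unbiased Hs
values and H_T = 2q̄(1−q̄) from the unweighted mean frequency **plus the
unbiasing term (Hs₁/m₁ + Hs₂/m₂)/4**. The term matters: without it,
H_T computed from sample frequencies is biased downward by ~Hs/2m
(≈ 0.007 at 36 copies), which swamps genuine differentiation of order
0.01–0.02 and erases the distance signal the IBD analyses regress on.
Ratio-of-sums (not mean of per-site ratios) avoids instability at
low-diversity sites; negative pair totals are clamped to 0. The
unweighted q̄ is appropriate for the near-equal locality sizes this
package targets.

Private alleles are counted at the allele level (either allele, absent
from every other group) and corrected by (n+1)/n. Regional summaries
report mean ± SE with SE = SD(n−1)/√k.

## Individual structure

Relatedness is a correlation-form moment estimator on complete-case
SNPs: centre each dosage by 4q̂ and take the normalized cross-product
over loci. It is bounded in [−1, 1] with unit self-relatedness and is
invariant to allele relabelling; it is *a* method-of-moments
estimator, chosen for those properties, and does not reproduce any
specific external program's values. PCA operates on column-centred
dosages (covariance of allele frequencies between individuals;
unit-variance scaling available but off by default), with signs fixed
so each component's largest-magnitude loading is positive —
bit-reproducible output under fixed input order.

## IBD vs IBE

Genetic distance is F_ST/(1−F_ST); geographic distance is the natural
log of haversine km (the log base only rescales β, never Mantel r);
environmental distance is Euclidean on z-scored covariates, after
greedy collinearity pruning at |r| > 0.9 (remove, from the worst pair,
the variable with the larger mean absolute correlation; ties by name).
Covariate importance ranking uses each covariate's single-variable
Mantel r against genetic distance — a transparent substitute for
machine-learning importance scores, and labelled as such.

Mantel tests correlate lower triangles and permute rows/columns of one
matrix jointly (999 permutations, one-sided greater,
p = (1+#{r* ≥ r})/(n+1)); the partial variant correlates OLS residuals
on the control matrix, recomputing the permuted matrix's residuals
each time. MMRR regresses the response triangle on predictor
triangles, with β and R² significance from permuting the response
matrix (1,000 permutations, |t| and F exceedance). Raw-scale and
standardized βs are both reported, since conventions differ.
Commonality analysis refits the two single-predictor models:
U₁ = R²_full − R²(Y~X₂), U₂ symmetric, C = R²_full − U₁ − U₂; the
identity U₁ + U₂ + C = R²_full is asserted to 10⁻⁹ on every call.

Two calibration caveats, both measured in the tests: response
permutation ignores the spatial autocorrelation of genetic distance,
so the per-predictor test is mildly liberal (~9.5% rejection at
nominal 5% for a spatially unstructured null covariate); and when the
environment is itself a latitudinal gradient — as the generator's
covariates are by construction — β_ENV inherits geographic signal
(~20% rejection under an IBD-only truth). That confounding is exactly
what the commonality decomposition is for, and why the package reports
it alongside MMRR rather than β values alone.

## Selection scan

Population frequencies (called dosages aggregated per locality) are
standardized per locus by the size-weighted mean:
z_j = (p_j − p̄)/√(p̄(1−p̄)), loci monomorphic overall excluded. The
population covariance Ω = ZᵀZ/L is shrunk 5% toward its diagonal to
guarantee invertibility (duplicate or near-duplicate populations
otherwise make it singular). XtX = zᵀΩ⁻¹z is approximately χ²_J under
the scan's neutral Gaussian model; the environmental association is
the Pearson correlation of Ω^(−1/2)-whitened z with the
Ω^(−1/2)-whitened z-scored covariate — a deterministic, desk-scale
surrogate for Bayes-factor association scores, monotone in association
strength, and stated as a surrogate in all outputs.

Thresholds come from pseudo-observed datasets: 100,000 neutral loci
with p̄ resampled from the empirical spectrum, z ~ MVN(0, Ω),
frequencies back-transformed, clamped, and **re-standardized through
the identical code path as real loci** (avoiding calibration bias from
clamping). Applied back to the PODs the 99%/99.9% thresholds exceed at
1.0%/0.1% by construction. Transferred to data from the logit-normal
generator they exceed at ~2%/0.25–0.4%: the generator's drift variance
scales as [p(1−p)]², not the p(1−p) the standardization assumes, so
real-locus XtX is a χ² scale mixture with a heavier tail. The tests
assert this measured behaviour; under Wright–Fisher-scaled drift (and
in the scan's own model) the calibration is exact. Outlier flags:
"conservative" = XtX above its 99% POD quantile with some |assoc|
above its 99.9% quantile; "very conservative" = the same with the
99.9% XtX quantile; XtX-only exceedances are flagged separately.

## Pipeline

`PipelineConfig` is the single source of every default (depth 5, 10%
missingness, MAF 0.05, 999/1,000 permutations, |r| > 0.9 pruning,
100,000 PODs at 99%/99.9%); configs round-trip through YAML and are
validated against the field list. `run()` executes enabled stages in
dependency order, writes TSV/VCF/JSON outputs plus a manifest with
SHA-256 content hashes, and is bit-identical under a fixed config —
asserted by hashing two runs in the tests.

## Problem sizes

The default benchmark is 16 localities × 9 individuals × 2,000–5,000
loci with 20,000–50,000 PODs and 99–999 permutations in tests; the
full-size defaults (100,000 PODs, 999/1,000 permutations) remain the
analysis-time settings. These sizes were chosen so the whole suite
doubles as a fast regression harness while leaving the statistics
well-resolved (Monte-Carlo error well inside every asserted band).

## What passing tests do not show

The generator has no linkage, no L-shaped MAF spectrum, no missing-
data structure correlated with genotype (dropout), no mapping or
assembly artefacts, and drift that is logit-normal rather than
Wright–Fisher. Accuracy figures measured here therefore transfer to
real data only qualitatively: calling concordance should be better on
real spectra, while POD calibration on real data depends on how close
real drift is to the scan's Gaussian model — the standard caveat for
every FLK-family scan.
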