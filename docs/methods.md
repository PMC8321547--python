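# Methods

This note documents the models behind each stage, the parameter defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Site table and filters

All frequency-based stages operate on a table of biallelic SNPs with
per-population alternative-allele counts and called-allele numbers.
"Frequency" always means the alternative (non-reference) allele frequency:
the discovery filter's thresholds (≥ 0.7 in the target breed) are above
0.5 and therefore cannot refer to the minor allele; the derived allele
relative to the reference assembly is the quantity of interest.

Hard filters follow the GATK convention (QD < 2, MQ < 40, FS > 60,
MQRankSum < −12.5, ReadPosRankSum < −8). A site failing several rules is
counted once in the total but attributed to every failed rule, so
per-rule counts are reproducible regardless of rule order. Missing
annotations pass (and are logged): rank-sum annotations are undefined at
sites without heterozygotes, and treating them as failures would silently
remove well-genotyped sites.

The presence filter retains sites genotyped in at least 25 % of samples
(inclusive boundary). Undefined frequencies are excluded from downstream
stages, never imputed: the presence filter defines the data quality floor
and imputation would manufacture information below it.

Coordinates: VCF input is 1-based; all internal interval types (tracts,
genes, masks) are 0-based half-open for BED interoperability.

## Allele classification

The discovery filter keeps sites with target frequency ≥ `target_min_freq`
(default 0.7) and every contrast population ≤ `contrast_max_freq`
(default 0.1), both boundaries inclusive.

A discovered allele is *present* in a reference group if at least one alt
allele was observed in any population of the group. It is *absent* only
when zero alt alleles were observed **and** at least 25 % of the group's
alleles were called (a group parameter, `presence_threshold`): absence
must never be declared from missingness. *Low frequency* means the
maximum population frequency in the group lies in (0, 0.1).

The category decomposition is hierarchical and exhaustive: an allele
absent from every non-target group is target-specific; one present in the
European taurine group at < 10 % is low-frequency-in-EU; the remainder
(absent from EU, present somewhere) splits by precedence into
found-in-Bovinae → African/Chinese-taurine → Hanwoo-only → indicine-only.
The precedence makes the four subcategories a partition of the
absent-from-EU set, which is what the reported percentages (shares of the
absent-from-EU count) assume. Presence in indicine breeds is additionally
reported as a cross-cutting flag. Report percentages are rounded half-up
to two decimals.

The cross-species conservation score for a missense change is
`(n_species_matching_alt − n_species_matching_ref) / column_depth` over an
orthologous alignment column: positive values mean the alternative amino
acid is the evolutionarily preferred state.

## Ancestry tract algebra

Tracts carry a carrier fraction — the share of haplotypes in the
population assigned that ancestry within the tract — and the headline
summary is the carrier-fraction-weighted base-pair share of the unmasked
genome. SNP–tract overlap uses half-open convention (a SNP at the tract
start is inside; at the end, outside).

The shared-allele filtering re-analysis removes every tract intersecting
at least one allele from any "shared" set (Bovinae, African/Chinese
taurine, Hanwoo) unless the tract also contains an indicine-specific
allele; tracts intersecting no classified allele are retained, since there
is no evidence against them.

Gene assignment sums a gene's span overlap with each ancestry class's
merged tracts and assigns at ≥ 60 % of the gene's total length (inclusive;
a gene may satisfy several classes).

The interval-overlap permutation test places query intervals uniformly at
random within their own chromosome (lengths preserved — conservative for
chromosome-scale structure), measures total overlapping base pairs, and
reports the add-one estimator `p = (1 + #{null ≥ observed}) / (n_perm+1)`
so p is never zero, with fold = observed / null mean. Default 10,000
permutations.

## FLK scan

Reynolds distances use the biallelic ratio-of-sums form
`D = Σ(pX−pY)² / Σ(1 − pX·pY − qX·qY)`; ratio of sums, not mean of
per-site ratios, so monomorphic sites do not dilute the estimate. The
population tree is neighbour joining on these distances with negative
branch lengths clamped to zero (standard practice; keeps the drift
transform defined), midpoint-rooted. Branch drift is `t = −ln(1−d)`,
additive along root-to-tip paths; the kinship entry `F_ij` is the summed
drift over the shared root path, `F_ii` the total root-to-tip drift.

The per-site statistic is
`T = (p − p̂₀·1)ᵀ F⁻¹ (p − p̂₀·1) / (p̂₀(1−p̂₀))` with
`p̂₀ = (1ᵀF⁻¹p)/(1ᵀF⁻¹1)` (the generalised-least-squares ancestral
frequency). Under neutral drift T is approximately χ² with `n_pops − 1`
degrees of freedom; sites with `p̂₀ ∈ {0,1}` (monomorphic across all
populations) are excluded. A singular kinship gets a 1e-9 diagonal jitter
(logged).

Calibration assumes selected regions are a small outlying fraction of the
genome: location and scale come from Huber's joint M-estimate (tuning
constant 1.345, the default of the robust fitter this procedure is
usually run with; ≤ 50 iterations, tol 1e-8), the statistic is
Z-transformed and upper-tail normal p-values are taken (one-sided, since
selection inflates T; a flag switches to two-sided). Because the
single-marker T is χ²-shaped rather than normal, the default FLK
calibration first applies the Wilson–Hilferty cube-root normalisation
`(T/ν)^{1/3} ≈ N(1−2/(9ν), 2/(9ν))`; fitting a normal directly to a χ²
scan would turn ordinary heavy-tail null markers into spurious signals.
q-values use Storey's smoother (λ grid 0.05–0.95 step 0.05, cubic
smoother evaluated at the largest λ), falling back to Benjamini–Hochberg
(π₀ = 1) when the π₀ estimate is unusable.

Interval calling is hysteresis on the q track: every maximal run of
markers with q ≤ 0.1 containing at least one marker with q < 0.01 becomes
an interval bounded by its outermost markers; the first marker with
q > 0.1 on either side is excluded. Overlapping intervals merge by
construction.

## Windowed F_ST

Weir & Cockerham (1984) two-population variance components a, b, c are
computed per site from diploid genotype counts (observed heterozygosity
enters the c component), windows of 10 kb slide by 5 kb, and each window
reports both the weighted ratio of sums Σa/Σ(a+b+c) and the mean of
per-site ratios. Negative estimates are reported as computed, not
clamped. Top extraction takes the ceiling of fraction × N windows by mean
F_ST, ties broken by (chrom, start).

## Context-dependent dN/dS

Every possible single-base coding change is enumerated per gene and
labelled synonymous/missense/nonsense (standard nuclear codon table,
coding strand from the annotation) and assigned one of 96
strand-collapsed trinucleotide context classes. Neutral rates are
observed synonymous counts per class divided by the genome-wide
synonymous opportunity of that class; classes without opportunity are
pooled to the global rate (logged). Expected gene counts are sums of
class rates over the gene's opportunities, giving
`ω̂ = (n_mis/E_mis)/(n_syn/E_syn)` — invariant to the overall rate scale.

Two p-value modes: the default is a profile Poisson likelihood-ratio test
of ω = 1 (saturated two-count alternative), one-sided by halving the χ²₁
tail on the side of the deviation, so a gene exactly at expectation gets
p = 0.5 on both sides; `method="exact"` gives exact Poisson tail
probabilities conditional on the synonymous rate, useful when
expectations are small. Benjamini–Hochberg q-values are computed per
direction across genes. Tests run at two frequency strata (breed alt
frequency ≥ 0.1 and ≥ 0.6), the higher stratum isolating variants likely
to affect the whole breed. This is a deliberate simplification of the
dNdScv family of methods: no negative-binomial gene random effects and no
covariates; nonsense variants are counted but not tested.

## f3 / D statistics

`f3(X;A,B) = mean (x−a)(x−b)` and
`D = Σ(a−b)(x−y) / Σ(a+b−2ab)(x+y−2xy)` over sites with defined
frequencies in all named populations. Standard errors are delete-one
block jackknives over contiguous genomic blocks (default 5 Mb); the D
jackknife leaves out block sums of numerator and denominator jointly.
Estimators are frequency-based without small-sample ascertainment
corrections, matching multi-sample breed panels; the known positive
sampling bias of f3 is small against the admixture signal at the panel
sizes used here. Admixture is flagged at f3 Z < −2 (a negative statistic
at two standard errors), the convention of the source analyses.

## Convergent-residue tests

The contingency path crosses the binary residue state with the binary
phenotype, reports `OR = (n11·n00)/(n10·n01)` (continuity-corrected +0.5
and flagged when a cell is zero) and the two-sided exact hypergeometric p.

The phylogenetic logistic regression models
`logit P(Y=1) = b0 + b1·X` with correlated binary residuals: the latent
correlation between tips decays as `exp(−α·d_ij)` in patristic distance.
Coefficients solve generalised estimating equations by Fisher scoring;
the working correlation is the latent decay attenuated by the linearised
binarisation factor `c_i = φ(Φ⁻¹(μ_i))/√(μ_i(1−μ_i))` (binary
correlation ≈ ρ·c_i·c_j for thresholded Gaussians), and α is estimated
by least-squares matching of standardised-residual products to that
model, iterating α and β to convergence. A weak ridge penalty (default
0.25, i.e. a vague normal prior with sd 2 on the logit scale) keeps
quasi-separated data sets — common when a rare residue is strongly
phylogenetically clustered — from diverging; `ridge=0` with a large fixed
α reproduces ordinary logistic regression exactly, which is the model's
no-signal limit.

Standard errors come from a parametric bootstrap of the fitted model
(Gaussian-copula binaries with the fitted marginals and latent
correlation). The p-value for b1 is a parametric bootstrap under the
no-association null in which **every resample is refit in full, α
included**, so the p reflects the variability of the whole procedure;
p uses the add-one estimator. Tjur and McFadden pseudo-R² are both
reported (computed from independence likelihoods).

## Synthetic data: what it emulates, and what it does not

* **Drift**: ancestral frequencies Uniform(0.05, 0.95) (avoids
  monomorphic sites), then Balding–Nichols Beta transitions along each
  branch (`Var(p_child|π) = F·π(1−π)`), implemented through paired Gamma
  draws so fixed frequencies propagate. Closed-form moments make the
  generator property-testable (the variance identity is asserted to
  ±0.002 at 50,000 sites).
* **Genotypes**: Binomial(2, p) per diploid sample, independent across
  samples and sites — no linkage disequilibrium. The analysis stages are
  frequency-based, so LD realism is unnecessary for their contracts; LD
  *does* matter for the real-data standard errors of f3/D, which is what
  the block jackknife is for.
* **Introgression**: within donor tracts the recipient's latent frequency
  becomes the carrier-fraction mixture of donor and recipient
  frequencies; truth tracts are returned for evaluation. `admix_population`
  applies the same idea genome-wide for f3-style scenarios.
* **Sweeps**: a hard plateau — the focal population's frequency set to
  the target at the locus and a shoulder (default 2) of flanking markers.
* **Coding genes**: random open reading frames with every possible coding
  change mutating independently at probability `mut_prob`, times ω for
  missense changes; ω = 1 is the neutral null of the dN/dS stage.
* **Phylogeny + trait**: random coalescent trees rescaled to root-to-tip
  depth 100 time units (the scale of a calibrated mammal phylogeny in
  millions of years, so rates and α have interpretable magnitudes);
  residue states follow a symmetric 2-state Markov chain (default rate
  0.02 per unit, giving realistically clustered states); phenotypes are
  Gaussian-copula Bernoullis whose marginals are exactly
  `invlogit(b0 + b1·X)` with latent correlation `exp(−α·d)`.

Passing tests on these generators demonstrates the estimators' contracts
under the assumed statistical structure; they do not demonstrate
robustness to LD, ascertainment, reference bias or genotyping error in
real resequencing data.

## Problem sizes and study conditions

The statistical checks run at the following sizes (chosen as desk-scale
study conditions; seeds fixed in the tests, derived from `--seed` in the
acceptance script):

* FLK null calibration: 6 populations, branch drift F = 0.01, 10,000
  diploids per population, 50,000 sites. The weak-drift, large-panel
  regime is where the χ²₅ reference of the single-marker statistic is
  exact enough for a 50,000-site uniformity test; stronger drift visibly
  skews the Beta transitions away from the Gaussian approximation the
  statistic relies on.
* Sweep recovery / null interval rate: 100 runs of 4,000 markers,
  6 populations (F = 0.01, 2,000 diploids), sweep to 0.99 with shoulder 2
  against a 0.5 background, kinship re-estimated from the data each run.
* Weir–Cockerham oracle: 1,000 random two-population genotype
  configurations against an independently written scalar implementation,
  tolerance 1e-12.
* dN/dS neutrality: 1,000 genes × 150 codons, per-change mutation
  probability 0.02.
* f3 admixture: 50 runs, parents at F = 0.2, 50/50 admixed target,
  20,000 sites; D null: 100 runs, 10,000 sites.
* Phylogenetic regression: type-I error from 500 null replicates at
  80 tips with 99 bootstrap resamples each; slope recovery from 100
  replicates at 200 tips (b1 = 2, α = 0.05).

## Known limitations

* The FLK stage is single-marker: the haplotype-cluster layer of the
  haplotype-based scan it descends from is out of scope, so power against
  soft sweeps is lower.
* The dN/dS stage is a simplified context-normalised Poisson test, not a
  full dNdScv reimplementation.
* The phylogenetic regression's working correlation uses a linearised
  binarisation attenuation; it is accurate for moderate correlations and
  is validated end-to-end by the type-I and recovery simulations rather
  than by analytic guarantees.
* Local-ancestry tracts are consumed, not inferred; the tract-filtering
  re-analysis reproduces the set algebra only.
* Real-data pseudo-R² of a published 113-species analysis depends on the
  external calibrated phylogeny and is not a reproduction target; the
  regression is validated by simulation instead.
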