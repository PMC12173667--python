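# Methods

This note documents the models, the generative assumptions, the numerical
choices and the known limitations of `topform`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The synthetic study

The generator stands in for a post-search top-down proteomics cohort: its
defaults are the study conditions the pipeline is designed for, and they are
fixed — the generator is a model of the data, not a tuning dial.

**Reference database.** `make_reference_db` draws target proteins across
three annotation tiers (canonical 89%, splice-isoform 7%, tentative 4% —
the proportions observed among identifications in cohort-scale studies) and
derives one full-permutation decoy per target (identical length and
composition, `DECOY_` accession prefix). Per-residue structural-confidence
(pLDDT) tracks alternate high-confidence domains (72–95) with low-confidence
linkers (25–45); linker segments are recorded so that cleavage placement can
be biased into disordered regions. Two hand-built fixtures are always
available: an APP-like 770-mer whose residues 672–713 carry the 42-residue
amyloid-beta segment, and a VGF-like 615-mer with eight dibasic convertase
motifs, thirteen "previously described" internal cleavage sites and four
planted novel sites. Both fixtures are synthetic stand-ins; only the
amyloid-beta segment and its APP coordinates are real.

**Cohort.** `make_cohort` assigns samples to batches by filling batches to
capacity `ceil(n/b)` (103 subjects in 6 batches gives 18/18/18/18/18/13).
Phenotype marginals follow the cohort table of the emulated study:
postmortem interval Gamma(mean 6.9 h, SD 4.6 h), tangle density
Gamma(6.3, 7.0), global cognition Normal(−0.83, 1.0), decline slope
Normal(−0.015, 0.097), binary pathologies at their printed prevalences, and
female sex assigned by exact count (`round(0.6117 · n)`), reproducing
63/103. Amyloid load is modeled Normal(4.7, 1.5) clipped at zero rather
than with its skewed empirical SD of 4.8: the generator's contract includes
a configurable amyloid–cognition Pearson correlation (default −0.5), and a
skewed marginal under a Gaussian copula attenuates Pearson r; the
correlation contract was kept and the marginal shape traded away. PMI is
drawn independently of all traits.

**Proteoform layer.** Each present gene spawns a truncation ladder
(`1 ∨ Poisson(7)` forms; the APP and VGF fixtures get fixed, designed
ladders covering the amyloid-beta x/y grid and the planted VGF cleavage
sites). A form is full-length with probability 0.12, Met-excised with 0.08,
otherwise truncated, with cleavage bonds drawn from linker regions with
probability 0.8 — this plants the low-pLDDT cleavage signal the annotation
stage is designed to detect. Modification classes are sampled independently
at the study frequencies (N-terminal acetylation 26%, lysine acetylation
4%, oxidation 3%, phosphorylation 2%, deamidation 1%, pyroglutamate 1%).
Pyroglutamate is sampled unconditionally on the N-terminal residue identity
so that the marginal-calibration property applies uniformly to all classes;
a biochemical generator would condition on E/Q. Monoisotopic masses come
from pyteomics plus fixed modification deltas.

**Abundance model.** True log2 abundance of proteoform *g* in sample *s*:

    y_gs = gene baseline + proteoform offset + batch shift(s)
         + pmi_slope_g · PMI_s + Σ_t effect_gt · z(trait_t)_s
         + loading · module factor_m(s) + ε,  ε ~ N(0, 0.5²)

Batch shifts are N(0, 0.5²) per batch; 10% of proteoforms carry a PMI slope
of ±0.05 log2/h; each configured trait plants effects (default 15
proteoforms at 0.4 log2 per trait SD for amyloid, tangles, cognition); six
modules of 10–80 members share latent N(0,1) factors with unit loading,
giving within-module correlations near 0.8. Effect sizes are zero for all
other (null) proteoforms.

**Observation layer.** Intensities are `2^y` with 5% multiplicative
measurement noise; a cell's intensity is *missing not at random* with
probability `expit(−1 − 1.5 · z(y))` (lower abundance → more missing,
~30% overall), reproducing the completeness spectrum qualitatively.
Spectral counts are negative-binomial with mean proportional to relative
abundance (per-proteoform mean count log-normal around 4) and quasi-Poisson
dispersion φ = 2, so dispersion estimation is genuinely exercised; the
emulated study states the count model, not the generative dispersion. A
PrSM row is emitted per count; E-values of true matches are
`0.05 · Beta(0.2, 20)` (respecting the search ceiling), and incorrect
matches — assigned to decoys and to the configurable fraction of target
genes that are absent from the sample (default 15% present-fraction
complement) — draw E-values Uniform(0.001, 1) with low cross-sample
multiplicity. Absent target genes are what make a *true* gene-level FDR
measurable: an accepted target gene with no true signal is a countable
false discovery, with decoys behaving statistically identically. Per-run
retention-time drift is a monotone piecewise-linear warp with ≤ 10% local
slope deviation plus a run offset; masses are perturbed with 3 ppm Gaussian
error.

What the generator does **not** emulate: correlated PTM co-occurrence,
charge-state/isotope interference, chromatographic peak shapes, shared
peptide evidence across homologous genes, and realistic E-value/score
calibration curves. Passing tests therefore demonstrate the pipeline's
statistical machinery under the stated model, not instrument-level realism.

## Identification filtering

Gene score = minimum E-value over the gene's PrSMs. Within each annotation
tier the sorted gene scores are scanned and the largest cutoff with
conservative estimate `(decoy genes + 1)/target genes ≤ q` (default 1%) is
selected; targets rank before decoys at tied scores (documented optimistic
tie-break; ties have measure zero under continuous E-values). A tier with
no decoy genes provides no estimate — its maximum gene score is accepted
and the `1/T` floor is reported. The descriptive five-level report uses the
plain `D/T` estimator; the sequence level strips bracketed modification
tokens from the proteoform string (the remaining subsequence retains the
truncation coordinates). The estimator needs on the order of `100·(D+1)`
target genes per tier before any cutoff can certify 1%; tiers too small to
certify reject everything, which is the honest behaviour of the guarantee
at desk scale — default analyses therefore use ≥ 300 genes, with the
canonical tier carrying ~89% of them. Parsimony is greedy set cover with
ties broken canonical > isoform > tentative, then lexicographically; greedy
is within one of the exhaustive minimum on all shipped fixtures and
property-tested instances.

## Alignment, clustering, quantification

The run with the most accepted PrSMs is the reference; anchor pairs are
per-proteoform median RTs shared with the reference, smoothed by LOWESS and
projected onto a non-decreasing map by isotonic regression, evaluated by
linear interpolation (identity fallback below 5 anchors). Clustering first
collapses repeat spectra of the same (gene, proteoform string, run) to one
representative point — repeat acquisitions of a single eluting species
carry no clustering information — then forms exact connected components of
the predicate |Δmass| ≤ 0.8 Da ∧ |ΔRT| ≤ 2 min within each gene
(vectorized adjacency; windowed sweep above 4000 points). Cluster ids are
ordered by gene and minimum member mass, making the partition invariant to
input row order. The RT window (2 min) is a package default: the emulated
study specifies the mass tolerance but no RT window. Match-between-runs
fills unidentified cells with the nearest feature by |Δmass| then |ΔRT|
within the same tolerances; identified cells are never overwritten.
Intensities are log2 ratios against the per-proteoform across-sample
median. Completeness thresholds are expressed as fractions of the cohort
(50/103 for intensities; the count filter reads "3 batches with at least
two counts" as ≥ 2 counts within each of ≥ 3 batches — the per-batch
reading of an ambiguous phrase, flagged here). The network stage uses the
separate "more than 50 samples" threshold (51/103), kept as a distinct
configuration key.

## Batch correction

Parametric empirical-Bayes location/scale adjustment: per row, least
squares of the observed cells on batch indicators plus optional covariates;
standardization by the batch-size-weighted grand mean and pooled residual
SD; per-batch means and variances shrunk toward moment-fitted normal /
inverse-gamma priors via the standard coupled posterior iteration
(tolerance 1e-4, 200 iterations); adjustment `(z − γ*)/δ*`,
de-standardization, and finally re-centring of each row to its original
grand mean. The re-centring is a deliberate deviation from the stock
Bioconductor implementation (which preserves the grand mean only
approximately); it makes intercept-only correction exactly mean-preserving
while leaving batch-mean equalization and covariate preservation untouched.
A unit test compares row-centred output against `sva::ComBat` through
Rscript (agreement to ~1e-3, limited by the two solvers' stopping rules).
Degenerate cases: a single batch is a no-op; noiseless rows (zero residual
variance) floor the variance at 1e-12 and skip shrinkage when the
hyperprior moments vanish; rows with < 2 observed values in a batch fall
back to the prior-mean scale. Missing cells are excluded from estimation
and remain missing. Replicate dispersion is reported as median percent
relative SD on the linear scale recovered from the log2 ratios (sample SD).
Counts are never batch-corrected; batch enters the count model as a
covariate.

## Association testing

*Intensity:* per proteoform per trait, OLS of the log2 ratio on trait +
covariates (default PMI) over observed cells, skipping proteoforms with
fewer than (parameters + 2) observations. Residual variances across
proteoforms are modeled as s² ~ s0²·F(d, d0); d0 and s0² are fitted by
matching the mean and variance of log s² to the log-F distribution
(trigamma inverse by Newton iteration); when the observed spread is no
larger than the sampling noise the prior df is infinite and all variances
collapse to the pooled mean — which also makes the moderated t collapse
exactly to the ordinary t when all variances are equal. Inference is a
two-sided t on d + d0 degrees of freedom.

*Counts:* per proteoform per trait, Poisson IRLS (statsmodels GLM) with log
link, linear predictor trait + batch indicators + PMI, and offset
log(total accepted PrSMs per sample) — the offset normalizes for sampling
depth and can be disabled. Dispersion φ = Pearson χ²/df; the Wald statistic
divides the coefficient by `bse·√φ` and is referred to a t distribution on
the residual df. With φ fixed at 1 this reproduces plain Poisson Wald
statistics exactly. Non-convergence, constant traits and all-zero rows are
skipped with recorded reasons.

BH adjustment is applied within each (trait, quantification-mode) family by
default — matching a per-column significance reading of an association
punchcard — with the global family available. Binary and ordinal traits
enter numerically as given.

## Co-abundance modules

Preprocessing: completeness filter (≥ 51 samples by default), per-row OLS
residualization on PMI (observed cells), iterative rank-5 SVD imputation
(row-mean start, convergence at relative change < 1e-5 or 100 iterations),
then row z-scaling. Network: adjacency |cor|^β with β = 6 (unsigned), kept
fixed rather than selected by scale-free fit — the emulated analysis ran
the clustering tool at defaults; automatic selection is out of scope.
TOM_ij = (Σ_u a_iu·a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij); average-linkage
clustering of 1 − TOM with a static cut at height 0.99 and a minimum module
size of 5 (the smallest module reported by the emulated study) replaces the
dynamic hybrid tree cut — a documented simplification that recovers planted
block structure exactly in the test suite. Modules whose eigengenes are
closer than 0.15 in correlation distance are merged iteratively (closest
pair first). Eigengenes are the first right-singular directions of the
module submatrix, scaled to unit variance and oriented to positive mean
member correlation; the unassigned pool is excluded from module–trait
correlation (Pearson, t-transform p, BH across the module × trait family).

## Annotation

Truncation coordinates imply cleavage sites: an N-terminal cleavage at bond
start−1 when start > 1 (except Met excision, start = 2 on a Met-initiated
reference), a C-terminal cleavage at bond end when end < length. Sites
within the first or last three residues are excluded from structural
analysis. The "±3 residues" flank of a cleaved bond i is read as the six
residues i−2…i+3 — a bond has no central residue, so the seven-residue
reading was rejected; windows are clipped at termini and require ≥ 4
residues. Site flank means are compared to the pooled per-residue pLDDT of
all contributing proteins by a two-sample Kolmogorov–Smirnov test (the
emulated analysis shows a distribution shift without naming a test; KS is
the assumption-light choice), reporting the median shift and the fraction
of site means below 50. Amyloid-beta labels use the fixed anchor
x = start − 671 (position 1 = APP residue 672); C-termini 42/43 form the
plaque-associated class, ≤ 40 the vascular-amyloid class, and y = 41 is
left unclassified because the two groups are defined as ≤ 40 and {42, 43}.
Dibasic maps enumerate KK/KR/RK/RR bonds, report the observed-cleavage
coverage fraction and the novel sites absent from an optional known-site
list. Fisher's exact test is computed by direct hypergeometric enumeration
(two-sided by summing tables no more probable than observed), with a
Haldane 0.5 odds-ratio correction for zero cells; it is cross-checked
against scipy and against factorial-form enumeration in the tests.

## Problem sizes and determinism

Default analysis scale: 300 target genes (one decoy each), ~1,700
proteoforms, 103 samples, six batches — chosen so every stage, including
the FDR guarantee, operates in its intended regime while a full end-to-end
run completes in about two minutes on one core. The FDR-guarantee
measurement uses 20 studies of 300 genes at 24 samples (the guarantee
concerns gene counts, not cohort depth). All randomness flows from integer
seeds through `numpy.random.default_rng`; identical (config, seed) pairs
reproduce outputs byte-for-byte, and pipeline stages communicate only
through plain-text files so any stage can be re-run reproducibly from its
persisted inputs.

## Known limitations

- The gene-FDR guarantee is certified per tier; tiers with fewer than
  ~100·(D+1) target genes reject everything rather than over-promise.
- The quasi-Poisson Wald t is asymptotic; at very low counts (< ~2 mean)
  its size drifts, which the calibration tests avoid by testing at
  moderate means.
- The static tree cut can split one planted module into adjacent clusters
  before merging; merging at 0.15 usually heals this, but module counts on
  weakly separated structure are sensitive to the cut height.
- Match-between-runs transfers the nearest feature without a decoy-based
  transfer-FDR; transferred cells are flagged so downstream users can
  exclude them.
- The annotation stage treats the reference coordinates as exact; it does
  not reconcile ±1.00235 Da isotope errors or localize ambiguous
  modifications.
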