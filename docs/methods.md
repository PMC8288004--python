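# Methods note

This note documents the statistical model behind `adaptscape`, the synthetic
data generator used as the package's study system, the main numerical
choices, and known limitations. The target application is comparative
landscape genomics of a host–parasite plant pair (a temperature-associated
mistletoe on a precipitation-associated host shrub) in an arid gradient
landscape, but every component is generic.

## 1. Pipeline overview

For each species the pipeline runs, in order:

1. **QC** (`adaptscape.genotypes.run_qc`) — locus missingness < 5%,
   technical reproducibility > 0.98, minor allele frequency > 5%, individual
   missingness < 20%, then seeded random thinning to one SNP per sequenced
   fragment. All thresholds are strict inequalities and the order is fixed,
   because MAF and individual missingness change as loci are removed.
2. **Climate predictors** (`adaptscape.climate`) — values are extracted at
   the sample coordinates from raster layers (cell containing the point),
   then pruned within each variable group (temperature, precipitation) by
   pairwise Spearman correlation: while any |ρ| ≥ 0.8 remains, drop the
   variable with the largest mean absolute correlation.
3. **Genome scans** (`adaptscape.scans`, `adaptscape.bayes`) — three scans
   with different operating characteristics (section 3).
4. **Consensus** (`adaptscape.consensus`) — loci significant in ≥ 2 scans are
   *adaptive*; loci significant in none are *neutral*; the rest are
   *single-method* and excluded from both sets.
5. **FST** (`adaptscape.fst`) — Weir–Cockerham (1984) θ, multilocus
   ratio-of-sums, computed separately on the adaptive and neutral subsets and
   min–max scaled to [0, 1] as the GDM response.
6. **GDM** (`adaptscape.gdm`) — generalized dissimilarity modelling with
   three order-2 I-splines per predictor, non-negative coefficients, a
   geographic-distance predictor, permutation-based backward elimination,
   and exact deviance partitioning across predictor groups.
7. **Spatial comparison** (`adaptscape.spatial`) — fitted splines transform
   the climate rasters into genetic-importance surfaces; PCA of the surfaces
   gives an RGB composition map; Procrustes superimposition of adaptive onto
   neutral maps quantifies where adaptive turnover decouples from neutral
   structure; residuals are min–max scaled across species jointly so the two
   maps share a scale.

## 2. Synthetic data generator

### 2.1 Model

Neutral loci follow a **Balding–Nichols model with spatially structured
populations**. Per locus, the ancestral frequency is drawn uniformly on
(0.05, 0.95) (adaptive loci: logistic cline, below); population frequencies
are Beta(p(1−F)/F, (1−p)(1−F)/F) marginally. Instead of drawing populations
independently (exchangeable structure), population deviates are coupled
through a Gaussian copula with correlation

    corr = h1·R1 + h2·R2 + (1−h1−h2)·(s·exp(−d/ρ) + (1−s)·I)

where R1/R2 are block matrices of a primary/secondary regional split
(north/south or east/west halves of the sampled populations), d is
inter-population distance, and ρ a range parameter. Beta quantile
transformation of the copula deviates preserves the Balding–Nichols
marginals exactly. This produces the leading features of real
reduced-representation data in structured landscapes — a dominant regional
ordination axis, isolation by distance, and a scree elbow — which an
exchangeable single-F model cannot (it has no preferred structure axis, so
PCA-based scans and latent-factor corrections behave pathologically).

Correlated population frequencies attenuate the Weir–Cockerham estimate, so
the target FST is calibrated: with c = 0.95 × mean off-diagonal copula
correlation (0.95 absorbs the shrink from the quantile transform), the
Balding–Nichols F that yields an expected multilocus θ = t is
F = t / (1 − c + c·t). Measured recovery at defaults: θ̂ ≈ 0.049 at t = 0.05
and ≈ 0.301 at t = 0.30.

**Adaptive loci** get population frequencies expit(β·z_v), where z_v is the
standardized population mean of the driving climate variable — a hard
logistic cline on the driver, independent of the neutral structure, plus
binomial sampling noise.

**Climate rasters** are planar gradients at a specified compass direction,
normalized to unit spatial standard deviation, scaled by an amplitude, plus
Gaussian-smoothed local noise (~40% of the variance share at defaults):
bioclimatic layers are locally heterogeneous, and without local noise all
same-group variables would be exact monotone transforms of one another.

**Sampling artefacts**: genotypes are masked missing at rate 1.2%,
fragments carry 1–3 SNPs (40/35/25%), reproducibility scores are drawn from
(0.985, 1.0) with a 2% contamination from (0.90, 0.98), so every QC filter
has real work to do.

### 2.2 Study conditions (defaults)

`default_pair_configs` fixes the study system: 10 populations × 15
individuals, 2000 neutral + 10 adaptive loci, effect β = 3.

* **Host**: F = 0.08, driver `annual_precip`, mild east/west substructure
  (region weight 0.25). The host's structure axis is deliberately not
  aligned with its ~N/S precipitation driver, as in systems where host
  scans succeed at low differentiation.
* **Parasite**: F = 0.30, driver `temp_seasonality`, dominant north/south
  divide (region weight 0.8) — strong hierarchical structure partially
  confounded with the temperature gradient, the hard case.

These are *study conditions*, not tuning knobs: they encode the qualitative
contrast the package is built to analyse (strongly differentiated
temperature-driven parasite vs weakly differentiated precipitation-driven
host) and were chosen from the mechanics of the scans, not from test
outcomes.

### 2.3 What the generator does not emulate

No linkage beyond the fragment label, no selfing/clonality, no drift
history (frequencies are one Balding–Nichols draw, not a forward
simulation), no genotyping-error matrix beyond missingness and the
reproducibility score, and climate layers are stationary planes plus smooth
noise rather than real terrain-driven fields.

## 3. Genome scans

* **PCA outlier scan** (pcadapt-style): genotypes are mean-imputed,
  binomial-scaled, regressed on the top-K unit-variance principal
  components; the K z-score vectors per locus are combined into a
  Mahalanobis D² using the OGK robust location/scatter estimate
  (median/MAD based); p-values use a χ²_K with genomic-inflation correction
  λ = median(D²)/median(χ²_K), and significance is Storey q < 0.05.
* **Latent-factor ridge scan** (LFMM-style): run **once per climate
  variable**. For variable x, genotypes are projected off x by ridge
  regression, latent factors are the rank-K SVD of the residual, and the
  locus test is the OLS z-score of x in the design [1, x, U_K], with its own
  genomic-inflation λ = median(z²)/0.4549 and per-variable
  Benjamini–Hochberg q < 0.05. Running variables jointly would test partial
  effects, which collapse under population-level collinearity (7 covariates,
  10 populations).
* **Bayesian environmental association** (BayPass-style): a
  Metropolis-within-Gibbs sampler for the population-allele-frequency
  covariance model (inverse-Wishart Gibbs step for Ω; reflected random-walk
  for per-locus α and π), XtX differentiation statistic calibrated against
  pseudo-observed data simulated under the fitted null (3%/97% quantiles),
  then importance-sampling Bayes factors for each standardized covariate
  over a uniform β grid on (−0.3, 0.3) with 101 points, averaged across
  chains; dB = 10·log₁₀(BF) ≥ 20 (decisive on Jeffreys' scale) is
  significant. The aux scan conditions on an Ω refitted on XtX-non-outlier
  loci only.

**K choice**: the number of latent factors/PCs uses a scree-gap rule —
the largest K whose eigenvalue drop (λ_K−λ_{K+1}) exceeds 5% of the total
fall (λ_1−λ_{k_max}) — **floored at K = 2** in the pipeline. With ≥ 10
sampled populations a single structure axis never suffices, and the gap
rule returns K = 1 whenever one axis dominates; empirical Cattell choices
in comparable datasets are 2–5.

## 4. GDM details

I-splines are order-2 with knots at the 0/50/100 percentiles of each
predictor (geographic distance uses pairwise haversine km). The link is
d = 1 − exp(−η), η = a₀ + Σ β|ΔI|, fitted by IRLS with non-negative least
squares inner steps minimizing binomial deviance. Backward elimination:
per predictor, site-level permutation of its values (coordinates for the
geographic term) with p = (hits + 1)/(n_perm + 1); the least-important
non-significant predictor is dropped each round at α = 0.05. If no climate
variable survives, the pipeline refits force-retaining the most important
one so the subset can still be mapped; the forced variable is flagged in
the run manifest. Deviance partitioning solves the inclusion–exclusion
linear system over all predictor-group subsets exactly, so unique + joint
components sum to exactly 100% of explained deviance (joint components may
be negative, as usual for variation partitioning).

## 5. Numerical and scale choices

Default problem sizes are desk-scale so the full two-species analysis runs
in ~2 minutes on one core: MCMC 2000 iterations (1000 burn-in, 2 chains,
thin 5), 1000 pseudo-observed loci for XtX calibration, 100 permutations
for backward elimination. Publication-scale settings (100k iterations,
50k burn-in, 4 chains, 500 permutations) are available via
`RunConfig(paper_scale=True)`; the desk-scale defaults are a package design
choice, not a statistical claim — dB thresholds and permutation p-values are
noisier at desk scale.

Determinism: every stochastic step derives its generator from
`np.random.default_rng([seed, offset])` with fixed per-stage offsets, so a
given seed reproduces byte-identical artifacts.

## 6. Known limitations

* **Consensus power at high differentiation**: at parasite-like FST (~0.3,
  10 populations) the two-of-three consensus has measured power ≈ 0.6 on
  planted β = 3 clines (five study-condition seeds). The Bayesian scan flags
  every planted locus decisively, but a second corroborating method is
  knife-edge: the PCA-outlier scan ranks planted loci at the very top yet
  the Balding–Nichols background's own heavy differentiation tail keeps
  their q-values near 0.05, and the latent-factor scan's genomic-inflation
  correction (λ ≈ 9–35 at K = 2) absorbs most of its power. This is an
  honest property of consensus scanning under strong, simple
  (linkage-free) structure; real data with linkage blocks and
  locus-heterogeneous differentiation behaves more favourably.
* **Bayesian scan null rate**: at dB ≥ 20 the expected-Bayes-factor (Markov)
  bound guarantees P(BF ≥ 100) ≤ 1% under the null; observed null rates at
  desk-scale MCMC are ~1–2% (importance-sampling and short-chain noise),
  not the ≪1% a calibrated frequentist test would give. Interpret dB
  thresholds as evidence grades, not error rates.
* **Procrustes comparison** requires both adaptive and neutral maps, hence
  ≥ `min_adaptive_loci` (default 3) consensus loci per subset and at least
  one retained climate variable; small adaptive sets skip the map with a
  logged warning.
* The Weir–Cockerham estimator is unbiased, not non-negative: identical
  populations give small negative θ̂, and the scaled [0,1] response maps the
  smallest observed value to 0 by construction.
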