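# Methods

This note documents the statistical models, numerical choices and known
limitations of `latvar`.  Everything stated here is recomputed by the test
suite or by `scripts/acceptance.py`; no number is quoted from elsewhere.

## Indices

**Lateralisation index.**  LI = (R − L)/(R + L) on a non-negative bilateral
pair; antisymmetric under hemisphere swap, invariant to common positive
scaling, bounded in [−1, 1] with equality exactly when one side is zero.  A
zero denominator (both sides zero) is a degenerate pair: it is recorded as
missing with a warning, never as ±inf or NaN propagation.

**Variability index.**  VI = (MAD_R − MAD_L)/(MAD_R + MAD_L), where MAD is
the *raw* median of absolute deviations from the sample median.  No 1.4826
consistency factor is applied: the definition is literal, and any common
factor cancels in the ratio anyway.  Even-length medians are the mean of
the two central order statistics (the standard convention).  VI < 0 means
greater left-hemisphere dispersion across individuals.  Note the
consequence that a single-participant sample has MAD 0 in both hemispheres,
hence an undefined VI.

**Missing data.**  A failed tract reconstruction removes all three metrics
of that tract × hemisphere together; this invariant is enforced at I/O
time.  The default assembly policy is *listwise*: a participant missing any
tract is excluded from the LI matrix entirely (mirroring cohorts that drop
participants with incomplete reconstructions, e.g. 172 → 164 retains
95.35%).  A *per-feature* pairwise policy is available behind a flag; the
VI/permutation machinery is always pairwise per tract × metric because it
needs no cross-feature alignment.

**Hemisphere-averaged comparisons.**  The three global (per-metric)
variability tests average the 7 tract values per hemisphere within each
participant (participants with all 7 tracts bilaterally present), then
apply the same VI + permutation machinery to the per-participant means.
The alternative — pooling all tract values per hemisphere before the MAD —
would mix across-tract with across-participant dispersion; the
per-participant mean is the more literal "hemisphere-averaged" reading and
is the one implemented.

**Multiple comparisons.**  The family is fixed at 24 tests (21 tract-level
+ 3 global); the per-test threshold is α/24 = 0.05/24 ≈ 0.0021, applied as
a strict `p < α` rule.  The family size does not shrink when individual
tests cannot run (missing data), so the correction never becomes more
liberal on degraded inputs.

## Hemisphere-swap permutation test

The null hypothesis is within-participant exchangeability of (L, R).  Each
of `n_perm` permutations independently swaps each participant's pair with
probability ½ (pairing across participants is never broken) and recomputes
VI; the two-sided p-value is the proportion of permuted |VI| ≥ observed
|VI|, ties counted as extreme.  With the strict `p < α` decision rule this
raw-proportion estimator is correctly sized (the acceptance study measures
the type-I error over 2000 exchangeable cohorts at n_perm = 999 and finds
it inside the 95% binomial band around 0.05).  A zero count is reported as
p = 1/n_perm with `p_is_floor=True` rather than p = 0 — consistent with
reporting conventions like "p < 0.00001" at 100 000 permutations; the
conservative smoothed estimator (count+1)/(n_perm+1) is available via
config.  Degenerate permuted samples (both hemispheres constant, only
possible for pathological inputs) count as maximally extreme.

An exact enumerator over all 2^n swap patterns (n ≤ 16) is the small-n
oracle; the Monte-Carlo count is exactly Binomial(n_perm, p_exact), which
is what the oracle-agreement study checks (deviations in binomial SEs).  A
degenerate *observed* VI is an error in the Monte-Carlo test; in the exact
enumerator at n = 1 every pattern is equally degenerate, an all-tie
enumeration, so p = 1.

RNG discipline: one master seed; each test in the 24-test family draws from
`SeedSequence([seed, stream_index])` with a fixed documented stream table,
so results are order-independent and individually reproducible.

## Bayesian lateralisation inference

Likelihood: LI values i.i.d. Gaussian(μ, σ).  H1 places a Cauchy(0, 0.707)
prior on μ truncated to [−1, 1] (the LI range; scale 0.707 is the common
"medium effect" default), and a half-Student-t(df = 3, scale = 2.5) prior
on σ *in both models*; H0 fixes μ = 0.  BF10 = exp(log ML₁ − log ML₀).
The half-t dispersion prior is the common weakly-informative default of
hierarchical-regression software; a prior-scale sweep
(`prior_robustness_sweep`) quantifies sensitivity to the μ-prior width, and
the same function pattern applies to σ by constructing `PriorSpec`s with
other `SigmaPrior`s.

**Quadrature.**  Marginal likelihoods are deterministic tensor-product
integrals: σ via inverse-CDF (prior-quantile) Gauss–Legendre nodes, μ via
prior-quantile nodes inside the truncation interval.  Node counts start
from a width heuristic (how much prior mass the likelihood bump occupies)
and are doubled until successive grids agree to relative 1e-6; the residual
change in log BF is reported as `numerical_error`.  Beyond order 512 a
composite 32-point-panel rule replaces a single Gauss rule (the
eigen-decomposition behind huge Gauss rules is cubic in the order).  Since
there are no Markov chains, this grid-refinement estimate plays the role
that R-hat and trace inspection play for MCMC fits.  Posterior mean, SD and
central 95% interval of μ come from a fine marginal grid (a
highest-density interval is available by flag).

**Cross-checks (independent routes).**
* *Prior-sampling Monte Carlo* (`bayes_log_bf_mc`): σ is drawn from its
  prior by stratified inverse-CDF sampling; for each draw the μ-integral is
  evaluated in closed form as a Voigt profile (Gaussian × Cauchy
  convolution, `scipy.special.voigt_profile`) minus explicitly integrated
  truncation tails.  Rao–Blackwellising μ this way is what makes a 1e6-draw
  estimator sharp enough (|Δ log BF| ~ 1e-5) to validate the quadrature;
  naive joint (μ, σ) prior sampling has standard error ~0.05 on
  concentrated samples and would only validate loosely.
* *JZS oracle*: with the effect-size parameterisation (Cauchy(0, r) on
  δ = μ/σ, Jeffreys 1/σ prior, truncation widened to ±1e6) the model is the
  standard JZS one-sample construction, and the BF is checked against the
  textbook noncentral-t integral evaluated by adaptive quadrature.
* *Limits*: a vanishing prior scale collapses H1 onto H0 (BF → 1,
  Jeffreys–Lindley); this limit is approached once the prior scale is far
  below the posterior uncertainty of μ, so it is exercised on a moderately
  asymmetric sample.  Mirror symmetry (negating the sample leaves BF10
  unchanged) follows from the symmetric prior and is asserted exactly.

**Sample-size stability** (`sample_size_stability`) is a Bayes-factor
design analysis: for each n in a grid it simulates (or subsamples) LI
cohorts, fits the Bayes test, and reports the distribution of log₁₀ BF10
and the fraction of replicates with conclusive evidence (BF10 > 10 or
< 1/10 by default).  Under a true effect the conclusive fraction is
non-decreasing in n in expectation; under a true null, evidence for H0
accumulates instead.

## Synthetic cohorts

Each tract × metric is a latent bilateral Gaussian pair with correlation
ρ (Gaussian copula, default 0.5) pushed through a marginal chosen for the
metric's domain: lognormal for streamline/voxel counts (positive,
right-skewed; default latent sd 0.40/0.35 at medians 1000/5000),
logit-normal for HMOA (bounded in (0, 1); default latent sd 0.12 at median
0.10).  Controls and their calibration:

* **target mean LI** — the hemisphere offset starts at the analytic
  small-dispersion value 2·atanh(λ) (location ratio (1+λ)/(1−λ)) and is
  bias-corrected by up to six stochastic probe passes of 1e4 draws
  (tolerance 0.005 on the probe mean; verified accuracy < 0.02 over targets
  ±0.5).
* **MAD ratio** — the latent scales are split as s_L = s₀/√q, s_R = s₀√q
  with q solved *exactly*: the marginal MAD of a monotone transform of a
  Gaussian is available by deterministic root finding, so no probe draws
  are needed for dispersion (verified < 10% over ratios 0.5–2).
* **failures** — Bernoulli per tract × hemisphere per participant; all
  three metrics of a failed tract/hemisphere are missing together.

Strong mean asymmetry combined with *equal absolute MADs* is genuinely
unreachable for very dispersed lognormals (the right-tail variance needed
to equalise MADs destroys the mean asymmetry); the calibrator detects
non-convergence and raises an infeasibility error rather than silently
missing its targets.  The default latent sds are moderate precisely so the
documented calibration envelope (|target LI| ≤ 0.5 × MAD ratio 0.5–2) is
feasible.

`reference_scenario()` encodes a realistic operating regime: leftward
AFl/ILF/FAT and rightward AFa/UF mean asymmetries on all metrics,
near-bilateral AFp/IFOF, left-variable ILF/FAT and right-variable AFa/UF
macrostructural dispersion (MAD ratios derived from the intended VI via
(1+VI)/(1−VI)), per-feature LI spreads typical of each metric class
(latent scales set from the intended cross-participant LI SDs given
ρ = 0.5), n = 164, and a 0.0035 tract × hemisphere failure rate chosen so
~95% of participants survive listwise exclusion.  What the generator does
*not* emulate: cross-metric correlation within a tract (metrics are
conditionally independent given the failure process), outliers beyond the
chosen marginals, and any spatial/geometric structure — so passing tests
demonstrate correct statistical machinery under a plausible generative
model, not anatomical fidelity.

## Phenotype continuum versus clusters

UMAP (n_neighbors = 15, min_dist = 0.1, Euclidean, fixed recorded seed) is
used purely descriptively, via umap-learn.  LI features are passed
unstandardised by default — they already share the bounded [−1, 1] scale —
with z-scoring behind a flag.  Quantitative clusterability is computed on
the original 21-D LI space, never on the 2-D projection (which can both
fabricate and destroy apparent clusters):

* **Hopkins statistic** with plain (unexponentiated) nearest-neighbour
  distances against a uniform reference on the per-feature bounding box;
  ~0.5 for unstructured (uniform) data.  In 21 dimensions even a compact
  *unimodal* cloud sits somewhat above the uniform baseline (measured mean
  ≈ 0.63 for scenario cohorts) because uniform reference points in a
  high-dimensional box are far from any concentrated mass; strongly
  clustered archetype controls sit higher still (≈ 0.8).  Hopkins is
  therefore reported as supporting evidence, with the silhouette carrying
  the discrimination.
* **Silhouette** of k-means fits over k = 2..8; unimodal cohorts stay
  ≤ 0.3 while well-separated archetypes exceed 0.5, so the a-priori
  decision threshold 0.35 (the midpoint of those regimes) classifies
  unimodal versus bimodal cohorts with ≥ 95% accuracy at n = 164.

Rows are canonically sorted inside the clusterability computation, making
the metrics exactly invariant to participant order despite seeded
subsampling and k-means++ initialisation.

## Reproducibility and problem sizes

Every stochastic component takes a single master seed and derives
documented `SeedSequence` substreams per stage/test/replicate; report
bundles are byte-identical across reruns and carry a manifest (version,
command, config digest, seed, stream table, input digests).  Floats in
machine outputs are serialised at 17 significant digits; human-facing
tables round to 2–3 decimals with Bayes factors in scientific notation
(stored as logs internally — BF10 can exceed 1e40).

Validation studies use these problem sizes, chosen to pin each property
with comfortable Monte-Carlo margins while keeping a full run on one CPU
to a few minutes: 50 datasets × 20 000 permutations for the
Monte-Carlo/exact oracle; 2000 replicates × 999 permutations at n = 164
for the type-I error; 20 samples × 1e6 draws for quadrature-vs-sampling
agreement; 200 replicates for parameter recovery; 30 seeds for the
scenario sign pattern; 100 replicate pairs for clusterability
discrimination.

## Known limitations

* The Gaussian LI likelihood ignores the hard [−1, 1] support of LI; for
  the dispersions of interest (posterior mass well inside the interval)
  the effect is negligible, and the μ-prior truncation keeps the mean in
  range.
* The σ-prior family is fixed to half-t/Jeffreys; Bayes factors shift
  modestly under other dispersion priors (explorable via `SigmaPrior`).
* The "Est. Error" reported in `bayes.tsv` is the posterior SD of μ.
* UMAP coordinates are reproducible only for a fixed umap-learn version;
  the backend version is recorded in the embedding parameters rather than
  asserted.
* Hopkins ≈ 0.5 is a property of *uniform* data; do not expect it for
  compact unimodal clouds in high dimension (see above).
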