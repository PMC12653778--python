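# Methods

## The model

White leg markings are scored per limb either as affected/unaffected or on
a four-class ordinal scale (0 unaffected; 1 below the fetlock; 2 above the
fetlock; 3 up to the cannon bone). Both views are treated as threshold
traits: a latent liability

    l = X b + Z u + W m + e

underlies each limb's score, with `b` the systematic effects (sex, coat
colour, the pedigree inbreeding coefficient F), `u` the direct additive
genetic effect of the animal, `m` the maternal genetic effect of the dam,
and `e` an independent residual. The genetic effects are
pedigree-structured: `(u, m) ~ N(0, A ⊗ G)` with `A` the numerator
relationship matrix. The observed score is the index of the threshold
interval the liability falls in.

Heritability is reported on the liability scale as
`h² = σ²_u / (σ²_u + σ²_m + σ²_e)` — the maternal variance is part of the
denominator. Genetic correlations are `r = Σ_u[i,j] / √(Σ_u[i,i] Σ_u[j,j])`
computed per posterior draw; summaries are of per-draw ratios, never
ratios of summaries. The classical liability↔observed transformation
`h²_obs = h² z² / (p(1−p))` (with `z` the standard-normal density at the
prevalence threshold) is provided for the binary view.

### Identification

A threshold model is identified only up to an affine transform of the
liability. The binary model fixes the threshold at 0 and `σ²_e = 1`. The
four-class model fixes `t1 = 0`, `t2 = 1`, estimates `σ²_e`, and samples
the single free threshold `t3`. Reported variance components therefore
live on these conventional scales; `h²` and `r_g` are scale-free.
`markqg.simulate.model_scale_truth` maps any generator configuration onto
the fitted model's identified scale (an exact likelihood-invariant
mapping), which is how recovery tests compare estimates with truth.

## Estimation

### Threshold animal model (`ThresholdAnimalModel`)

Gibbs sampling with liability augmentation. Each cycle:

1. liabilities from normals truncated to the observed category interval
   (inverse-CDF draws with an exponential-rejection tail sampler; a
   pathologically narrow interval falls back to a uniform draw inside it,
   so no draw is ever NaN or escapes its interval);
2. location effects by single-site Gibbs over the sparse system embedding
   `A⁻¹` — fixed effects with flat priors, then a per-animal *block*
   update of the T-vector of direct effects (the joint T-dimensional draw
   keeps multi-trait chains mobile when genetic correlations are near
   ±1), then maternal effects (diagonal maternal covariance);
3. variance components: `σ² = q/χ²_{n−2}` with `q` the `A⁻¹` quadratic
   form (univariate), inverse Wishart `IW(n − T − 1, U'A⁻¹U)`
   (multivariate), residual from the residual sum of squares (four-class
   and gaussian scales only);
4. the free threshold `t3` from its uniform full conditional.

Three extra exact moves address the slow directions of this sampler:

* a Metropolis rescaling of `(u, Σ_u)` and of `(m, σ²_m)` by a common
  factor (the overall scale of a genetic-effect vector is the slowest
  mode of single-site sweeps);
* an interweaving (ASIS) re-draw of the Cholesky factor of `Σ_u` in the
  non-centered parameterization `u = ũ L'`, with multiplicative proposals
  on the diagonal loadings — this makes the covariance update
  likelihood-driven and prevents the centered draws from freezing the
  genetic correlations; step sizes adapt during burn-in only;
* for the four-class model, a collapsed global scale move that integrates
  the liabilities out (the exact categorical likelihood is a product of
  normal-CDF differences) and proposes a joint rescaling of all locations,
  variances and `t3`. With `t1, t2` fixed the latent scale is informed
  only by the class frequencies between them, and the augmented sampler
  alone random-walks along that direction extremely slowly.

All three are standard Metropolis-within-Gibbs moves targeting the same
posterior; determinism is preserved because every draw flows from one
`numpy.random.Generator` seeded by `ChainConfig.seed`, with a fixed sweep
order. Permuting input rows changes the stream and hence the draws — runs
are reproducible for a fixed input order and seed.

**Priors.** Fixed effects and thresholds: flat. Variances: flat on the
positive axis (`ν = −2, S = 0` scaled-inverse-chi-square). Covariance
matrices: flat on the positive-definite cone, the direct multivariate
analog (`ν₀ = −(T+1), S₀ = 0`). We deliberately avoid a "weak" inverse
Wishart with small positive degrees of freedom and a near-zero scale
matrix: that prior concentrates mass on singular matrices and drags
genetic correlations to ±1 (we verified the effect against an exact
marginal-likelihood oracle on an unrelated-animal fixture). All priors
are user-overridable on `ThresholdModelSpec`.

**Divergence and mixing guards.** A variance draw above 1e8 aborts with a
diagnostic. Geweke z-scores (`markqg.posterior.geweke_z`) are reported as
an automatable proxy for trace inspection, never enforced.

**Direct–maternal covariance.** The model statement includes σ_um, but no
estimate is reported for it anywhere, so it defaults to off (the
generator's null likewise). When enabled (univariate only), `(u_i, m_i)`
are updated with the exact 2×2 coupled conditionals and the covariance by
a 2×2 inverse-Wishart draw.

**Maternal structure in multi-trait fits** is diagonal by default; the
full maternal covariance is deliberately not sampled — at desk scale the
system is ill-conditioned long before a full 4×4 maternal covariance is
identifiable.

### Cumulative-logit risk model (`CumulativeLogitModel`)

Per-limb proportional-odds regression with a dam random intercept,
`logit P(Y≤j) = α_j − (x'β + d)`, fitted by Metropolis-within-Gibbs:
random-walk updates for β and α (ordering enforced by rejection),
parallel single-site updates for the dam effects (valid because dams
partition the records), and a multiplicative update for the dam SD with a
half-normal(5) prior. Priors on β and α are normal with scale 5. Effects
are screened by the equal-tailed 95% credible interval; an interval
touching zero does **not** exclude it. The reported sign convention is
the latent-severity orientation (positive β = more marking), which is the
negative of the textbook cumulative-logit slope.

The dam-SD interval is reported on the SD scale. Comparable published
screening intervals for the maternal term do not state their scale
(SD vs variance); consumers comparing numbers should check which scale
they need.

### Posterior summaries (`markqg.posterior`)

Mean/median/sample-SD per parameter, plus the empirical shortest-window
HPD interval: the `ceil(0.95 n)`-draw window of minimal width over the
sorted draws, ties broken toward the lowest window. This is deterministic
and matches post-Gibbs practice in animal breeding; no kernel density
estimation is involved.

## Pedigree algebra (`markqg.pedigree`)

* Inbreeding by Meuwissen–Luo ancestor tracing (exact, `O(n·depth)`),
  with ancestors processed youngest-first so every path coefficient is
  complete when consumed.
* Dense `A` by the tabular method, guarded above a configurable size.
* Sparse `A⁻¹` assembled directly by Henderson's rules with the Quaas
  inbreeding adjustment: Mendelian sampling variance
  `d = 0.5 − 0.25(F_s + F_d)`, an unknown parent contributing `F = 0`
  and `+0.25` (so 0.75 with one parent known, 1.0 with none). Unknown
  parents are unique unrelated founders.
* Ordering is a Kahn topological sort with input-order tie-breaking, so
  file order never changes results.

These conventions are the standard ones; the pedigree software used for
the published inbreeding coefficients does not document its unknown-parent
handling, so agreement is expected but not guaranteed for animals with
exactly one recorded parent.

## The synthetic generator (`markqg.simulate`)

The generator draws data under exactly the model the estimators fit:
discrete non-overlapping generations with random mating within generation;
joint `(u, m)` Mendelian sampling with variance `d_i · G`; liabilities
with the configured fixed effects; scores by thresholding. Coat colour is
assigned independently of the genetics — the generator emulates covariate
structure, not pigmentation biology.

The default preset (`pre_like`) encodes the study conditions: direct
genetic variances (4.877, 4.772, 7.904, 5.659) for LF/RF/LH/RH, maternal
variances (0.185, 0.130, 0.398, 0.273), diagonal residuals (4.000, 3.420,
8.046, 5.898), genetic correlations 0.991/0.995 within the fore/hind
pairs and 0.863–0.907 across, projected to the nearest positive
semidefinite correlation matrix by eigenvalue clipping (a rounded printed
correlation table need not be PSD; the projection is our choice).
Thresholds are placed so the marginal normal-CDF class probabilities
match the observed prevalences (5.29/4.65/17.95/14.51% affected, with the
published class shares), after centring the mean fixed-effect
contribution; the extra marginal variance contributed by the fixed
effects is ignored in this calibration, so realized prevalences are
approximate (within a few tenths of a percent). Effect sizes for sex and
coat are set from the published raw unaffected-percentage gaps on the
probit scale; the F slope (1.2 total-SD per 3 units) is of the order the
published foreleg credible intervals imply. Sex ratio 0.339 male and coat
frequencies (0.404, 0.387, 0.085, 0.125) follow the studbook composition.

What the generator does **not** emulate: overlapping generations, the
real population's mating structure (so simulated mean F at desk scale is
~0.01–0.03 rather than 0.074), molecular genotypes, and non-genetic
maternal environment distinct from the maternal genetic effect. Passing
recovery tests therefore demonstrate correctness of the estimation
machinery under the stated model, not robustness to violations of it.

## Problem sizes and numerical choices

Desk-scale defaults used by the tests and the reproduction script:
pedigrees of ~2,000–6,000 animals (150–400 founders, 3 generations),
chains of 8,000–16,000 iterations with 3,000–6,000 burn-in and thinning
4–6. The published analysis is two orders of magnitude larger (38,825
records, 83,334-animal pedigree, 100,000 rounds); its point estimates are
not desk-reproducible and are not test targets. Parameter-recovery
coverage (truth inside the 95% HPD in ≥ 90% of 10 seeded replicates) is
the substitute criterion.

Numerical details worth knowing:

* truncated-normal draws switch to Robert's exponential rejection beyond
  5 SD; the normal quantile uses Acklam's approximation with one Halley
  refinement (~1e−15);
* the four-class marginal prevalence pins the latent scale only weakly
  when the below-fetlock class is rare (~2% of records); the posterior
  for the absolute variance components is then wide and right-skewed at
  desk scale, while h² and r_g remain well determined;
* `ordinal4` requires every class observed at least once per trait; the
  risk model merely requires two observed categories and relabels;
* empty-category threshold conditionals are guarded (upper bound falls
  back to the lower bound + 1).

## Known limitations

* Single-chain inference; no multi-chain R-hat (matching the published
  single-chain workflow). Geweke is the only automated diagnostic.
* The multivariate maternal covariance is diagonal.
* σ_um is supported univariately only.
* The collapsed scale move assumes flat variance priors; with informative
  priors it is disabled implicitly only if you also change the Gibbs
  conditionals — override priors with care.
* Printed four-class heritabilities in the source material do not equal
  the ratio of the printed posterior-mean components, and the printed
  observed-scale heritabilities do not follow from the classical
  transformation; neither quantity is reproducible from published
  numbers, and neither is used as a target here.
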