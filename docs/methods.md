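# Methods

## The growth model

The response is the natural logarithm of annual scale increment width in
micrometres. This transform is the package's central modelling convention:
increment widths are strictly positive, right-skewed, and multiplicative in
age and group effects — a baseline near exp(6.70) ≈ 810 μm for a hatchery
freshwater year against exp(6.70 + 0.61) ≈ 1,490 μm for a hatchery first
sea year matches the magnitudes seen in spawning-run samples, which a
linear-scale model cannot do with a single additive coefficient per cell.

For increment *i* of fish *f(i)* grown in calendar year *t(i)* in
environment *e(i)* (freshwater or sea) by a fish of group *g(i)* (wild or
hatchery),

    log w_i = x_i'β + u_fish[f(i)] + u_year[g(i), e(i), t(i)] + ε_i

- **Fixed effects** x_i'β: age class (FW1 reference, so the intercept is
  the hatchery-FW1 baseline), group (hatchery reference), their
  interaction, optionally sex. Each coefficient therefore reads as a log
  ratio against the baseline cell.
- **u_fish ~ N(0, σ²_fish)** absorbs persistent individual differences
  (an individual "growth level"); its between-group variance ratio is the
  individual-plasticity statistic.
- **u_year ~ N(0, σ²_year)**, one intercept per group:environment:year
  cell, is the biochronology: the systematic deviation of that stratum's
  growth from its age/group expectation in that calendar year.
- **ε ~ N(0, σ²_obs)** is residual (measurement plus within-fish-year)
  noise.

Fixed effects carry independent N(0, 100²) priors on the log scale —
effectively flat at the data's scale of ±1.

### Priors on the variance components

Three families are implemented per component:

- `pc` (default for σ_fish, σ_year): the penalized-complexity prior, an
  exponential on the SD with rate λ = −ln(α)/U so that P(σ > U) = α.
  Defaults U = 1 (log scale), α = 0.01 — weakly informative; an increment
  SD of 1 on the log scale would mean ±170 % year-to-year growth swings,
  already implausible, and the data (thousands of increments) dominate.
- `half_cauchy` (scale 1 by default) for sensitivity analysis.
- `inv_gamma_default`: Gamma(shape 1, rate 5e-5) on the precision, the
  conventional "default" prior of hierarchical-model software; conjugate,
  and the default for σ_obs.
- `fixed` freezes a component, which turns the sampler's joint update into
  an exactly solvable Gaussian problem — the basis of the oracle tests.

`prior_sensitivity` refits under any set of families and tabulates the
spread; at the study's sample size fixed-effect posteriors are insensitive
to the family (the tests pin this), while on tiny datasets (tens of
increments) the SD posteriors differ visibly, as they must when the prior
dominates.

### Inference: blocked Gibbs

The posterior is the contract, not any particular approximation. The
sampler alternates:

1. **(β, u_year, u_fish) jointly** from their multivariate normal full
   conditional given the variances (the mixed-model normal equations).
   The fish block of the precision matrix is diagonal, so (β, u_year) —
   tens of dimensions — is drawn first from its marginal via a Schur
   complement, then each fish intercept from its univariate conditional.
   This is an exact joint draw, so mixing does not suffer from
   fixed-vs-random-intercept correlation, and one iteration costs a dense
   Cholesky of order (p + #cells) plus O(#fish) work.
2. **Each variance component** given the effects: conjugate gamma update
   for the `inv_gamma_default` family; stepping-out slice sampling on
   log σ for `pc` and `half_cauchy`.

Defaults: 2 chains × 1,250 post-burn-in draws, burn-in 600, which runs in a
few seconds at the study's size (3,800 increments, 1,596 fish, ~47 year
cells) and gives split-chain potential-scale-reduction below ~1.05 on the
hyperparameters; values above 1.01 trigger a warning with the diagnostics
attached. Identical seed + config give bit-identical draws.

### DIC and term selection

DIC uses the likelihood conditional on the latent effects (the convention
of the latent-Gaussian software family this analysis style comes from —
the "focus" matters, since marginalising the random effects would change
pD): D(θ) = −2 log N(y | Xβ + Zu, σ²_obs I), DIC = mean D + pD,
pD = mean D − D(posterior means). A term is supported if dropping it raises
DIC by more than 2.

Because our DIC is computed from sampler draws it carries Monte Carlo
noise, unlike DIC from a deterministic approximation. `dic_standard_error`
(batch means) quantifies it, and `compare_terms` reports it alongside each
ΔDIC; with latent-conditional deviance and ~400 effective parameters the
noise can reach a few units, so a null term's ΔDIC occasionally crosses
the ±2 line in either direction. The sex term, which the generator leaves
null, is compared and dropped in the default configuration.

## The synthetic cohort generator

The generator is the study-conditions definition, not a tuning knob. Per
fish: smolt age FW1/FW2 (0.899/0.101), sea age SW1/SW2/SW3
(0.630/0.351/0.019) — combinations listed as rare are excluded from the
regular draw and instead injected as explicit counts (default three 2.0+,
three 2.3+, one 3.1+, giving 1,603 caught / 1,596 analysed) — group
(wild with probability 449/1596, from the plasticity-test group sizes), sex
(female 1249/1596), capture year uniform on 2007–2016. Repeat spawners
(10.7 % overall) are drawn among fish with ≥ 2 sea winters, and their last
completed sea zone is marked as spawning-eroded (width shrunk by a factor
0.7; the value is irrelevant since the zone is filtered). Every fish
carries one marginal plus-growth zone, simulated as a uniform 0.2–0.8
fraction of a full next sea year. This composition *emergently* reproduces
the filtering fractions (~28.7 % marginal, ~3.0 % spawning) and the
2003–2015 growth-year span.

Zone widths follow the model above with the published coefficient table as
default truth (σ_obs = 0.155, σ_fish = 0.058, σ_year = 0.065). Year
effects are coupled to yearly temperature: with z_temp the
sample-standardised series of the zone's environment,
effect = σ_year (ρ z_temp + √(1−ρ²) z), so the population correlation is
exactly ρ per (environment, group) — defaults 0.41/0.29 at sea and
0.21/0.05 in freshwater for wild/hatchery. Temperatures are normal draws
(optionally AR(1)) with sea mean 12.0 ± 0.7 °C (Jul–Dec) and freshwater
9.1 ± 0.5 °C (annual).

The fish table derives the scale radius as the sum of the fish's zone
widths; fork length is 17.128 + 0.013 × radius + N(0, 5.4²) cm. The noise
SD is set so the calibration OLS explains ~76 % of variance at the
generator's radius spread (which, at ~740 μm SD, is wider than a real
sample's ~500 μm because synthetic life histories mix freely). Circulus
counts are 0.0302 per μm of radius with SD-4 rounding noise, giving the
weaker R² expected of a discrete proxy.

What the generator does **not** emulate: within-fish ageing trends beyond
the age-class means, density dependence, survival/size selection,
measurement error correlated along a transect, and group-specific
σ_fish (both groups share one individual SD, so the pipeline's F test is
expected near 1 on synthetic cohorts; the F test's behaviour under a
planted variance ratio of 0.41 with group sizes 1,147/449 is exercised by
a dedicated intercept-level experiment). Passing tests therefore show the
estimator recovers its own generative structure at the study's size — not
that real scale data satisfy that structure.

## Calendar anchoring

Fish are caught in autumn on the spawning run, after the growing season:
the marginal zone is the capture year's (partial) growth, so completed zone
k of m gets growth_year = capture_year − 1 − (m − k). With captures
2007–2016 and retained life histories up to 2.2+, completed zones span
exactly 2003–2015. This is the unique convention consistent with that span.

## Chronologies, variance shares, plasticity, climate coupling

- `extract_chronology` is a pure function of the posterior draws; the draw
  matrix is retained because downstream tests need the joint posterior, not
  the summaries.
- Variance shares are posterior-mean SDs squared over their sum
  (σ²_k / (σ²_obs + σ²_fish + σ²_year)); with the published SDs this reads
  13 % year / 11 % fish, and the shares are invariant to rescaling the
  response.
- The plasticity F test compares sample variances of the *posterior-mean*
  fish intercepts, F = var_hatchery/var_wild with (n_h−1, n_w−1) df,
  two-sided by default (one-sided by flag). Using point summaries is the
  conventional two-step procedure and is known to be nonconservative; it
  is kept because the posterior-propagation machinery here targets the
  year effects, where the secondary test (the correlation) is the headline
  inference.
- `monte_carlo_correlation` correlates each posterior draw of a stratum's
  year-effect series with temperature over the overlapping years (Pearson
  default, Spearman by flag; n_draws default 1,000, subsampled with a seed
  if the posterior holds more). With a degenerate posterior it reduces
  exactly to the plain Pearson test of the mean chronology, and under a
  null coupling the plain two-step test rejects more often than the
  propagated one — both properties are pinned by tests.

## Numerical and design notes

- Tie-breaks and ordering: fish and year-cell indices are sorted, so
  draws, summaries and CSVs are byte-stable under a fixed seed.
- Degenerate inputs: a dropped random term yields empty draw blocks rather
  than errors; zero-variance temperature or < 3 overlapping years abort the
  correlation with a clear message; an empty exclusion result warns rather
  than fails.
- The slice sampler uses stepping-out with shrinkage (width 0.5, ≤ 50
  steps) on log σ, with the Jacobian term included; a pathological slice
  returns the current value rather than looping.
- Sample sizes in tests: the exhaustive recovery experiment runs at the
  full study size; shared fixtures use 150–400 fish so the whole suite
  stays fast, with recovery bars scaled to what shrinkage at those sizes
  supports.
- The realized correlation between a 13-year coupled year-effect series
  and temperature has sampling SD ≈ 0.3 around ρ; single-cohort analyses
  therefore report it next to the estimate, and population-level coupling
  recovery is only asserted over long simulated spans.
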