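# Methods

`repskew` measures and models sex-specific reproductive inequality —
how unequally surviving offspring are shared among same-sex members of a
group — across human populations and nonhuman mammal species. This note
documents the statistical model behind each component, the tunable
parameters that matter, the numerical choices, and what the synthetic
test bed does and does not demonstrate.

## The multinomial skew index M

For one group-sex cell with individuals `i = 1..n`, offspring counts
`rs_i` (total `K`) and positive exposures (years at risk, or age at
census), define the opportunity for selection `I = Var(rs)/Mean(rs)²`
(population variance). The null model allocates the same `K` offspring
multinomially across the `n` individuals with probabilities
`q_i = exposure_i / Σ exposure` — i.e., every individual reproduces at
the same rate per unit exposure — and the index is

```
M = n/(n−1) · ( I_obs − E_null[I] ).
```

`M = 0` means reproduction is distributed exactly as the null expects;
`M > 0` means it is more concentrated; `M < 0` means it is shared more
equally. Because the replicate total is fixed at `K`, the replicate
mean is exactly `K/n` and the null expectation has a closed form:

```
E_null[I] = (n/K)·Σ q_i(1−q_i) + n·Σ (q_i − 1/n)²,
```

which reduces to `(n−1)/K` for equal exposures (so the equal-exposure
index is simply `n/(n−1)·I_obs − n/K`). `compute_M` evaluates the null
either by seeded Monte Carlo (2,000 replicates by default — the
operational definition, and the route used for uncertainty-free
reproduction of the index as defined) or with the closed form
(`method="analytic"`); the two are cross-checked against each other in
the test suite.

Two deliberate conventions:

* **Population variance in `I`.** `opportunity_for_selection` uses the
  divide-by-`n` variance; the `(4, 0)` group has `I = 1`.
* **Finite-sample factor `n/(n−1)`.** Both the observed and the null
  statistic carry the same `(1 − 1/n)` attenuation from the population
  variance, so their raw difference shrinks toward zero in small groups
  — a pure estimator artifact that would masquerade as a group-size
  effect in cross-species comparisons. The factor removes it exactly;
  simulation (see the robustness tests) confirms that with it the mean
  index shows no trend over `n ∈ {10..200}` at fixed heterogeneity, and
  is invariant to doubling the mean fertility.

Degenerate inputs: a cell where every individual has `rs = 0` has no
defined skew; such cells raise a distinct `SkewUndefinedError` and are
excluded from batch tables with a logged warning rather than imputed.

**Transform.** Raw `M` values are heavy-tailed across species, so all
analysis and sex differences use `M* = sign(M)·√|M|`; per-group sex
difference is `M*_m − M*_f`.

**Published-statistic conversion.** Variance (`v/mean²`), SD
(`(sd/mean)²`) and CV (`cv²`) map onto `I`, which is then standardized
against the equal-exposure null with `K = round(n·mean_rs)`. Nonacs'
B-type indices — defined as the observed-minus-expected variance of
offspring shares `p_i = rs_i/K` — relate exactly to the index by
`M = n³/(n−1) · B` under equal exposure, since `Var(p) = I/n²` on both
the observed and null sides; the relation is verified against the
direct computation in the tests. Converted estimates are flagged
`source="converted"`.

**Uncertainty.** A nonparametric bootstrap over individuals gives the
SE and equal-tailed 89% percentile interval of `M`; resamples use the
exact analytic null so the bootstrap spread reflects sampling variation
only. Resamples with zero total offspring are dropped.

## The mating-market model

Males hold rival resources `R` (divided among a male's wives) and
nonrival resources `G` (conferred on all offspring); both are drawn
lognormal, independently across males, normalized to mean 1. The
lognormal is used because its Gini has the closed form
`2Φ(σ/√2) − 1`, so a target Gini is hit exactly in distribution
(`sample_resources` inverts it). A female married to male `i` with
`k_i` wives in total recruits offspring in expectation

```
w = (R_i / k_i)^μ · G_i^(1−μ),      γ = 1 − μ  (constant returns),
```

with female inputs uniform across individuals. `μ` is the fitness
elasticity of rival resources: at `μ = 0` cowives are costless, at
`μ = 1` fitness is proportional to the per-wife rival share.

**Male demand.** A male always accepts a first wife. Keeping a
polygynous household carries a one-time mating-investment cost equal to
a fraction `male_cost` (default 0.23) of his single-wife recruitment
`R^μ G^γ`: he takes a second wife only if her marginal recruitment
`(2^γ − 1)·R^μ G^γ` exceeds it, i.e. iff `2^(1−μ) − 1 > male_cost`.
Because the cost scales with the male's own output, the decision
depends on `μ` alone, and the demand side produces an emergent
monogamy regime at `μ ≳ 0.70` for the default cost — the regime where
dividing vital rival resources among cowives nearly halves everyone's
output. Alternative forms were examined: a fixed absolute per-wife cost
never binds for resource-rich males (no monogamous regime appears
anywhere), and a per-wife proportional cost truncates harems at two
wives just below the threshold, which *raises* the percentage of
polygynous men there by spreading wives across more males. The
entry-cost form is the simplest demand side that yields the intended
monotone surfaces; it is a design choice of this package.

**Equilibrium search.** `match_ideal_free` runs randomized sequential
best response: each female (random order per sweep) moves to the
willing male maximizing her prospective fitness, computed with his wife
count incremented by her arrival; ties favor the incumbent and then the
lowest male index; sweeps repeat until a fixed point (at most 500
sweeps, with non-convergence flagged, never silent). The terminal state
is a bilateral Nash equilibrium: no female can gain by unilaterally
switching to any willing male, and no male regrets his marginal wife
(`is_bilaterally_stable` certifies both). For markets of up to five
males and females, an independent brute-force enumeration of every
assignment (plain-Python, written separately from the vectorized
checker) serves as the oracle; the suite certifies best-response
outcomes against it on a thousand random markets.
`match_imposed_monogamy` instead bars females from joining paired
males: sequential choice in random order, each female taking the best
still-unpaired male; with equal sex ratios every male ends with exactly
one wife.

**Reproduction.** Matched females' expected offspring are their
Cobb-Douglas fitness rescaled so the matched-female mean equals
`fertility_scale` (default 2); realized counts are Poisson
(`offspring_mode="poisson"`), with a deterministic `"expected"` mode
for noise-free surfaces. Males receive the sum over their wives;
unmatched individuals are retained with `rs = 0` (skew is measured over
all adults); exposure is 1 — the model abstracts age structure away.
Under imposed monogamy with equal numbers, the male `rs` vector is a
permutation of the female one, so `M_m = M_f` identically.

**Sweeps.** `sweep` maps a grid over `(Gini of R) × μ × rule` to
replicate-averaged polygyny percentages and `M_m`, `M_f`, `M_m − M_f`
(analytic null, for exactness and speed), seeded per cell via spawned
seed sequences. The package default for full surfaces is a 25×25 grid,
200 males/females and 20 replicates per cell over
`Gini_R ∈ (0.12, 0.64)`, `μ ∈ (0.15, 0.95)` with `Gini_G = 0.12`; the
test suite exercises a 10×10 grid with 10 replicates, which resolves
all the qualitative structure.

## Bayesian meta-analysis

Group-level `M*` outcomes (male, female, or per-group sex difference)
are modeled as draws around class means:

```
y_g ~ Normal(θ_c(g), √(σ² + se_g²)),   θ_c ~ Normal(0, 1),   σ ~ HalfNormal(1),
```

with `se_g` an optional known measurement SD (zero unless
`use_measurement_error` is set; per-group bootstrap SEs are transported
to the `M*` scale by the delta method, with `|M|` floored at 1e-6 —
crude near zero, which is why the measurement-error model is off by
default). Classes come from the metadata grouping: taxon (human vs all
nonhuman mammals), the primate subset (fitted as its own model rather
than jointly — species in both mammal and primate classes would
otherwise appear twice in one likelihood), nonhuman mating system,
human marriage system, human subsistence, or polygynous-taxon
(normatively polygynous human populations vs polygynous species).
Groups observed for one sex only contribute to the sex-specific
outcomes and drop out of the sex-difference outcome.

Sampling is Metropolis-within-Gibbs, vectorized across 4 chains
(1,000 kept draws each after 500 warmup, seeded): the class means are
conjugate normal given `σ`, and `log σ` takes an adaptive random-walk
step tuned to ~44% acceptance during warmup. Summaries are posterior
means with equal-tailed 89% credible intervals (the package-wide
interval convention); contrasts are computed draw-by-draw, so
`contrast(A, B) = −contrast(B, A)` exactly. Every parameter reports
split-chain R-hat and bulk ESS (via arviz); fits violating the gates
(R-hat ≤ 1.01, ESS ≥ 400) are flagged, not suppressed. Frequentist
coverage of the 89% intervals at fixed true contrasts (0 and 0.5) is
verified by simulation in the acceptance tests.

The polygyny-intensity regression is a Bayesian simple linear
regression of male `M*` (or the sex difference) on percent age-adjusted
female polygyny, standardized internally with Normal(0, 1) priors on
the standardized coefficients; the fitted line's band is reported at
95%, the convention for that display. The robustness fit drops human
groups lacking the high-quality-demography flag and reruns the same
model, tagging the result with the subset name.

## Synthetic data

The generator emulates the *structure* of a comparative skew
compilation, never any real population's values; configured truths are
arbitrary and returned alongside the data.

* `gen_null_records` — multinomial allocation proportional to exposure
  (uniform, or an age-like 15–75 spread): ground truth `M = 0`.
* `gen_skewed_records` — gamma-Poisson: rates `~ Gamma(shape)` scaled
  to `mean_rs`, counts Poisson(rate × relative exposure). The family
  nests the null (`shape → ∞`) and, because the null standardization
  removes the Poisson `1/mean` term, has `E[M] ≈ 1/shape` independent
  of the mean rate and of `n` — verified by simulation. `gen_meta_dataset`
  in `"records"` mode inverts this map analytically
  (`shape = 1/M` for targets above a small floor) rather than by an
  empirical lookup; the inversion's accuracy is itself a test.
* `gen_meta_dataset` in `"direct"` mode draws group `M*` values
  Normal(class mean, `residual_sd` = 0.25–0.3) — the fast path for
  sampler calibration studies.
* `default_study_spec` — 90 human populations laid out over a joint
  marriage-by-subsistence table (marriage margins 43/33/14; e.g. all 9
  market-economy populations normatively monogamous) plus 49 species
  (8 monogamous / 41 polygynous, 12 primates), group sizes 50–400, and
  a 19-population human subset carrying the continuous polygyny
  covariate. Class truths are ordered like the broad comparative
  pattern (large sex differences in polygynous species; high, nearly
  sex-equal skew in monogamous species; modest skew in humans).

What passing tests do *not* show about real data: the generator draws
groups independently (no phylogenetic or regional correlation), uses a
single overdispersion family, symmetric residuals on the `M*` scale,
and a covariate unrelated to skew; real compilations violate all four,
and the meta-analytic model makes no attempt to correct for
non-independence across species.

## Pipeline and reproducibility

`run(RunConfig(...))` executes `synth`, `compute` (records → skew
table), `meta`, `sweep`, or `run_all` (synth → meta). The global seed
is expanded per stage via `SeedSequence(seed, spawn_key=(stage_index,))`
with fixed stage indices, so outputs are pure functions of config +
seed, and a stage rerun in isolation reproduces its files exactly; the
manifest written beside every run records the config echo, package
version and derived stage seeds. Every pipeline stage logs input
counts, exclusions and seeds through the `repskew` logger.

## Problem sizes used in the checks

Null calibration uses 500 groups (n = 50, K = 100, 2,000 null
replicates); rate/size invariance 250 groups per condition and 120 per
group-size level; mating surfaces a 10×10 grid × 10 replicates at 200
males; the Nash oracle 1,000 random ≤5×5 markets; interval coverage 150
replicate datasets per true contrast with 40 groups per class. These
sizes resolve each effect at the 3-standard-error level used in the
assertions while keeping a full run of the suite around a minute.

## Known limitations

* The exposure model is a single positive number per individual;
  age-specific fertility schedules are out of scope.
* The measurement-error option relies on a delta-method SE transport
  that degrades near `M = 0`.
* The mating model is one group in isolation: no norm evolution, no
  intergroup competition, no extra-pair paternity.
* Best-response dynamics are not guaranteed to converge in principle;
  non-convergence is surfaced and replicate averaging absorbs
  equilibrium multiplicity, but cycles are possible in adversarial
  parameter corners.
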