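# Methods

## Models and state space

All four model variants describe one gene with two independent alleles
sharing a single, well-mixed mRNA pool. Per-allele gene states and rates
(min⁻¹ throughout; transcription in mRNA·min⁻¹ per allele):

| variant | allele states | transitions | transcription |
|---|---|---|---|
| `one_step` | off, on | off↔on (*k*ₒₙ, *k*ₒff) | *k*ₜ in on |
| `one_step_leak` | off, on | as above | *k*ₜ in on + constitutive *k*₀ |
| `two_step_silent` | off, I, on | off↔I (*t*ₒₙ, *t*ₒff), I↔on (*k*ₒₙ, *k*ₒff) | *k*ₜ in on |
| `two_step_permissive` | off, I, on | as above | *k*₀ in I, *k*ₜ in on |

mRNA degrades at *k*_d per molecule. The cell state is the unordered pair
of allele states plus the mRNA count *m* ≤ *M* (default truncation
*M* = 2000), giving 3(*M*+1) states for two-state alleles and 6(*M*+1) for
three-state alleles. Allele configurations are enumerated as
lexicographically sorted pairs ((0,0), (0,1), …); the flat index is
`config_index · (M+1) + m`. Both alleles switch independently — transition
propensities carry the multiplicity of alleles in the source state — and
the default initial condition is both alleles fully off with no mRNA,
matching a resting cell before stimulation.

## Solvers

*Time courses.* `propagate` applies the action of the sparse generator's
matrix exponential (`scipy.sparse.linalg.expm_multiply`; the dense
exponential is never formed). The truncation is handled by zeroing
transcription at *m* = *M*; a tail-mass guard (default 10⁻⁸ at the
boundary) raises a `TruncationWarning` when *M* is inadequate, and
normalization drift beyond 10⁻⁶ is an error. `expm_multiply`'s internal
norm estimator draws from NumPy's global RNG, which is pinned around the
call so that propagation is bit-reproducible.

*Steady states.* `steady_state` solves **R**p = 0 by replacing one row of
the sparse generator with the normalization constraint and factorizing
(residual guard ‖**R**p‖∞ ≤ 10⁻⁹); long-time propagation is retained as an
independent cross-check (`method="propagate"`).

*Fast exact marginal.* Because the alleles are independent and mRNA decay
is first-order, the marginal distribution of the total mRNA count equals
the self-convolution of a single-allele marginal. `transient_marginal`
propagates the single-allele CME (2(*M*₁+1) or 3(*M*₁+1) states) by
uniformization in a numba kernel written against the banded structure of
the generator, with the truncation *M*₁ chosen adaptively from a
closed-form mean and a telegraph-style Fano estimate and doubled until the
boundary mass is below tolerance. Uniformization is used here because the
generator is strongly non-normal (a long transcription superdiagonal), so
resolvent-based accelerations are numerically unstable while the
uniformized jump chain is unconditionally stable; the iteration count is
of order Λ·t where Λ is the largest total propensity. Agreement with the
full two-allele `propagate` at the 10⁻⁸–10⁻¹⁰ level is asserted in the
test suite. `transient_mean` evaluates the exact time-dependent mean in
closed form by diagonalizing the tiny allele-state ODE — microseconds per
call; the fitting objective uses it as a pre-screen (see below).

## Estimators and constraint surfaces

The closed-form steady-state moments of the two-allele telegraph model,
the moment estimators (*b*_m = σ²/μ, *f*_m = μ/(*b*_m−1), with
*f*_m = +∞ reported for Poisson-like data *b*_m ≤ 1), the kinetic
estimators (*b*_k = *k*ₜ/*k*ₒff, *f*_k = 2*k*ₒₙ*k*ₒff/((*k*ₒₙ+*k*ₒff)*k*_d))
and their closed-form relative discrepancies are implemented exactly as in
the README. Two printed forms of the variance and burst-size-error
expressions circulating in the literature are typographically unreliable;
the forms used here are algebraically forced by requiring (i) exact
agreement with the CME steady state and (ii) internal consistency with
(kinetic − moment)/kinetic computed through the moment route — both
asserted to 10⁻¹⁰ or better in the tests.

For a linear mean–variance trend σ² = αμ + σ₀:

- σ₀ = 0: *k*ₜ = (α−1)(*k*ₒff+*k*ₒₙ+*k*_d)(1+*k*ₒₙ/*k*ₒff) puts the model
  exactly at Fano = α (checked to 10⁻⁹ over 10⁴ random points).
- σ₀ ≠ 0: *k*ₜ solves A·*k*ₜ² + B·*k*ₜ − σ₀ = 0 with
  A = 2*k*ₒff*k*ₒₙ/(*k*_d(*k*ₒₙ+*k*ₒff)²(*k*ₒₙ+*k*ₒff+*k*_d)) and
  B = 2(1−α)*k*ₒₙ/(*k*_d(*k*ₒₙ+*k*ₒff)). Two positive roots exist for
  σ₀ < 0; the small root vanishes as σ₀ → 0; non-positive roots are
  discarded with a debug log record.
- Bursty-regime curves: b(μ) = (α−1) + σ₀/μ and f(μ) = μ/b(μ),
  implemented literally. (For σ₀ > 0 this b(μ) is monotone decreasing
  toward α−1; a minimum at μ = σ₀/(α−1) is sometimes claimed for this
  curve, which the formula's own algebra does not support — we implement
  the formula and note the discrepancy rather than guess an intent.)
- `modulation_map` sweeps *k*ₒₙ (200 log-spaced points by default) for
  each *k*ₒff in {0.01, 0.02, 0.03, 0.05, 0.075, 0.1, 0.2}, under
  plausibility bounds *k*ₒff < 0.2, *k*ₒₙ < 0.1, *k*ₜ < 30, μ < 500 with
  *k*_d = 0.014, and reports burst-size and frequency fold-changes over
  the attained mean range.

## Distribution fitting

The fit target is the distribution of counts at a fixed post-stimulation
time (default 180 min, i.e. the 3-h measurement), computed from the
all-off initial state. The objective is the integrated absolute distance
between the model CDF (evaluated on integer support, no smoothing) and an
empirical CDF of the data — the Wasserstein-1 distance. The empirical side
is either the Kaplan–Meier/ECDF with a Greenwood 95% band (default) or an
Epanechnikov-kernel smoothed CDF (bandwidth by Silverman's rule, floored
at 1 mRNA); on our synthetic checks the two targets lead to
indistinguishable fits.

The genetic algorithm follows the classical configuration: population 200,
elite 2, crossover fraction 0.6, tournament selection (size 4), with an
ensemble of independent runs (50 by default) summarized as mean ± SD per
parameter. Internals that the classical description leaves open are fixed
as: log₁₀-scale parameterization (rates span decades), intermediate
(blend) crossover, Gaussian mutation with a linearly annealed scale
(0.35 decades → 10%), 150 generations with a 30-generation stall stop, and
per-run seed substreams spawned from the master seed (recorded in the
output). Three further implementation choices matter for cost and
robustness:

- **Mean pre-screen.** W1(model, data) ≥ |mean difference|, and the model
  mean at the fit time is available exactly in closed form; candidates
  whose mean is further from the sample mean than 0.75 sample SD are
  scored by that lower bound without a CME solve.
- **Seeded initialization.** Half the initial population has *k*ₜ solved
  (linearly, via the closed-form mean) to match the sample mean.
- **Hybrid polish.** Each run's winner is refined by Nelder–Mead, the
  standard hybrid step for GA pipelines, terminating when objective
  improvements fall below 0.1 W1 units — the reproducibility scale of the
  empirical CDF itself at n ≈ 10³, below which refinement only chases the
  noise of one sample.

Default search bounds: switching/activation rates in [10⁻³, 0.2] min⁻¹,
transcription ≤ 30 mRNA/min per allele, and degradation either
[0.006, 0.07] (fast-turnover, TNF-α-like) or [0.002, 0.006]
(stable-transcript, IL-1β-like). Candidates whose support exceeds the
adaptive truncation cap are penalized by their (large) truncated-CDF
distance rather than aborting the run — random GA candidates routinely
overflow any fixed truncation.

**Identifiability.** A single-time-point distribution constrains the
four telegraph rates only up to a ridge: (*k*_d, *k*ₒff) can trade off
leaving the observed distribution essentially unchanged, so steady-state
extrapolations (μ∞, and to a lesser degree *b*_k) inherit the sampling
noise of one dataset amplified along that ridge. At n = 1000 cells we
measured parameter sets differing by 40% in *b*_k and 30% in μ∞ whose
exact 180-min distributions are within W1 ≈ 3 of each other — less than
the W1 ≈ 4–8 distance between the truth distribution and one n = 1000
sample of itself. Ensemble spread across GA runs is therefore a feature,
not a convergence failure; narrowing the *k*_d bounds (e.g. from measured
half-lives) is the effective cure. This is why the bundled recovery check
on synthetic data can land outside tight recovery tolerances for
perfectly valid sample draws.

## Negative-binomial screening and trends

`nb_goodness_of_fit` tests counts against an NB fitted by profile maximum
likelihood (Poisson fallback when the sample variance does not exceed the
mean), pooling support cells to expected counts ≥ 5 and reducing the
degrees of freedom by the number of estimated parameters; gene-wise tables
apply Benjamini–Hochberg adjustment and skip genes with fewer than 10
non-zero cells.

Across conditions, `fit_mean_variance` fits σ² = αμ + σ₀ by OLS with an
optional robust loop that excludes points with residuals beyond
1.5·σ_residuals (batch-wise, hence order-invariant, stopping when the
residual scale reaches numerical noise), optionally preceded by a
Mahalanobis filter on the raw (mean, variance) cloud at the χ²₂ quantile
(threshold 0.05). The ordering filter → fit → robust refit is a choice;
the filter-vs-refit order is genuinely ambiguous in common practice.
Variances are unbiased (n−1). Burstiness trends fit variance and relative
frequency linearly and relative burst size both linearly and in semilog
scale (b against log₁₀ μ), keeping the better R²; high-confidence classes
use R² > 0.75 (variance), > 0.7 (frequency), > 0.5 (burst size). Slope
differences between two trends are tested by the interaction-term t-test
on the pooled regression — a documented, swappable choice. Burst
statistics from read counts carry no absolute mRNA scale and are reported
as relative quantities. `size_normalize` rescales each cell's count by
(population mean nuclear area)/(cell nuclear area).

## Synthetic data

`ssa_simulate` draws exact Gillespie paths of the two-allele network (the
same per-allele reaction description that builds the CME generator, so
each route is the other's oracle; agreement is tested both ways at KS
α = 0.01 with 5·10⁴ paths). Steady-state-aged cells use a burn-in of
10/*k*_d (≈ 14 half-lives). Per-path RNG streams are spawned from the
master seed via `SeedSequence`, making datasets reproducible at the
integer-count level and independent across conditions.

`generate_trend_series` sweeps *k*ₒₙ log-spaced at fixed *k*ₒff (default
0.1) and *k*_d (0.014), places *k*ₜ on the constraint surface for the
requested (α, σ₀), and simulates steady-state-aged cells; the truth table
stores the analytic (μ, σ²), which lie on the requested line by
construction. Conditions violating the plausibility bounds are skipped
with a warning.

`generate_nb_matrix` emulates scRNA-seq-like gene × condition × cell
counts: on-trend genes follow σ² = α_g μ with per-gene α; off-trend genes
re-draw the Fano factor independently per condition; a configurable
fraction of genes is constructed to fail the abundance (max mean ≥ 100)
or induction (≥ 2-fold vs the unstimulated baseline) filters, so filter
logic can be scored against exact generator truth.

`add_cell_size_noise` multiplies counts by lognormal relative nuclear
areas (unit mean). The default CV of 0.13 is calibrated so that for
high-Fano (bursty) genes cell size explains ≲ 7% of count variance — the
magnitude reported for smFISH data of the motivating genes; the synthetic
data do not otherwise model extrinsic noise, segmentation error, or
technical dropout, so passing tests speak to the intrinsic-noise machinery
only.

## Scaled-down study sizes in the bundled checks

The test suite exercises full-scale analytic checks (50 randomized CME
cross-validations, 10⁴-point surface sweeps, 5·10⁴-path SSA comparisons)
but scales the optimization studies to desk size: GA recovery uses 5 runs
of population 20 with ≤ 12 generations plus polish; the model-selection
comparison uses 10 replicate datasets of 500 cells with best-of-2 runs of
population 12 per variant. The model-selection truth is a two-step
permissive gene with a slow first step (*t*ₒₙ = 0.008, *t*ₒff = 0.02) and
slow second-step cycling (*k*ₒₙ = *k*ₒff = 0.005, *k*₀ = 0.8,
*k*ₜ = 6, *k*_d = 0.004): the permissive and fully-active phases then
persist on the 3-h scale, producing the distinct low-count shoulder that
the two-step model exists to explain. We verified that the best
achievable one-step approximation to this distribution sits ≈ 24 W1 units
away — about twice the n = 500 sampling noise — so the comparison is
decidable at this size; an earlier parameterization with fast first-step
closing left the distribution one-step-mimickable (best one-step ≈ 1.3
units away, far under the noise), which tests optimizer luck rather than
model structure.

## Known limitations

- Rates are constant in time; stimulus dynamics enter only through the
  initial condition and the measurement time.
- Exactly two alleles; no allele-extrinsic coupling, cell-cycle or
  division effects, and no nascent-transcript (transcription-site)
  observables.
- The kinetic estimators and constraint surfaces are one-step results;
  for two-step models only moment estimators apply.
- Steady-state extrapolation from single-time-point fits is ridge-limited
  (see *Identifiability*).
- `LinearTrend.r2` can be undefined (NaN) for degenerate constant-response
  fits; classification then defaults to low confidence.
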