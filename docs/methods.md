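# Methods

## Model and estimators

The two-parameter logistic (2PL) model gives item *g* a response curve
P(x=1|θ) = logistic(β₀g + β₁g·θ) with the latent trait θ fixed at N(0, 1) —
the identification convention under which marginal estimation operates.  The
package uses the slope–intercept parametrization throughout; the classical
difficulty b = −β₀/β₁ is available as a utility.

**Marginal maximum likelihood (MML).**  The marginal likelihood integrates θ
out of each response pattern's probability.  The integral is evaluated by
Gauss–Hermite quadrature rescaled to the standard normal (default 21 nodes,
configurable; exact for polynomial integrands of degree ≤ 41, which is ample
for logistic curves with |β₁| of a few units).  Response rows are collapsed
to unique patterns with counts, so estimation cost scales with the number of
distinct patterns, not subjects.  The optimizer is Bock–Aitkin EM — posterior
trait weights on the grid in the E-step, per-item Newton steps of a weighted
logistic regression (vectorized across items) in the M-step — run to a
log-likelihood change below 1e−6, followed by an L-BFGS polish of the full
marginal likelihood with the analytic score.  The polish makes the
first-order condition hold sharply, which the difference-covariance algebra
of the Hausman test implicitly relies on.  Starting values: β₀ from the
inverse logistic of the item means, β₁ = 1.  Probabilities are clipped to
[1e−12, 1−1e−12] inside likelihood code.  Items with a single observed
response category raise a data error naming the item; non-convergence is
flagged, never silent.

The MML covariance is the inverse *expected* Fisher information — not the
observed information, whose use can destroy the positive definiteness of the
difference covariance below.  The information I = n·Σ_patterns P(x)s(x)s(x)′
is computed by exact enumeration of all 2^G patterns whenever 2^G ≤ 2^20,
and otherwise by a seeded Monte-Carlo average over model draws (default 10⁶;
the draw count and seed are recorded).  Chunked evaluation keeps memory flat
in G.

**Limited information (LI / ULS).**  The observed margin vector **o** stacks
the G univariate positive proportions and the G(G−1)/2 pairwise joint
positive proportions; **e**(α) are their model-implied counterparts
(order-1 and order-2 trait integrals).  The estimator minimizes
(**o**−**e**)′(**o**−**e**) by Levenberg–Marquardt with the analytic margin
Jacobian Δ.  Whether the margin vector should also contain the univariate
margins is a genuinely open design point; the default includes them
(`margins="pairs+uni"`) for identification stability of the intercepts, and
`margins="pairs"` gives the strictly pairwise version.  The asymptotic
covariance is the identity-weight sandwich (Δ′Δ)⁻¹Δ′ΞΔ(Δ′Δ)⁻¹, where
Ξ[u,v] = (π_{u∪v} − π_u·π_v)/n is the multinomial sampling covariance of
the margins and π are joint positive probabilities up to order 4, computed
by quadrature.

**Common evaluation point.**  Both covariances are evaluated at the MML
estimates by default (the LI point is available via `cov_eval="estimate"`).
The ULS fit warm-starts at the MML estimates, which keeps the two estimators
on the same mode and orientation; no sign constraint is imposed on β₁.

## The Hausman statistics

d = α̂ − β̂ is formed per item (both parameters) for H_g and over all
discriminations for H_T; intercepts are excluded from the global test
because including them makes Σ_d rank deficient.  Σ_d = Σ_α̂ − Σ_β̂ on the
selected coordinates.  H = d′d is referred to a·χ²_b with a = Σλ²/Σλ and
b = (Σλ)²/Σλ², computed from tr(Σ_d) and tr(Σ_d²); b is continuous and
usually fractional, so the gamma-family chi-square is used for the tail.
Negative eigenvalues of Σ_d (possible in finite samples because it is a
difference of estimates) are retained in the traces — clipping them would
bias a and b — but a warning diagnostic is attached; when tr(Σ_d) ≤ 0 the
test is reported infeasible rather than silently returning NA.  The Wald
form d′Σ_d⁻¹d is deliberately not offered: Σ_d is routinely near-singular.

**Parametric bootstrap covariance.**  B = 200 samples (minimum 50) are
resimulated from the 2PL at the MML estimates; each is refitted with both
estimators (point estimates only, warm-started) and the sample covariance of
the difference vectors provides Σ_d for all items and the global test in one
pass.  Failed refits are redrawn with a fresh child seed up to 3·B total
attempts; more than 20 % failures abort with a bootstrap-unstable error.

Item-level p-values are reported raw; a Benjamini–Hochberg adjustment is
available as a reporting option but rejection-rate summaries use the raw
values.

A small utility reports the degrees of freedom of the limited-information
M2 goodness-of-fit test, G(G−1)/2 − G (margins minus free parameters),
e.g. 135 for an 18-item form.

## Synthetic-data generators

`simulate_2pl` draws θ ~ N(0,1) and Bernoulli responses from the item
curves; thetas are stored for simulation audits only.  The misfit generators
emulate two departures studied in the size/power experiments:

* **Non-monotone ICC**: c·logistic(−a(θ−(b−l))) + logistic(a(θ−b)) with
  defaults a = 4.25, b = 1.00, c = 0.25, l = 1.50 — it falls from a plateau
  of 0.25 to ≈ 0.04 near θ = 0 and then rises S-shaped to 1.
* **Bounded ICC**: c + (1−c)·l·logistic(a(θ−b)) with defaults a = 3.40,
  b = 0.50, c = 0.00, l = 0.70 — a 4PL-type curve with upper asymptote 0.70.

Both families are generators only; they are never fitted.

* **Gaussian-copula local dependence**: within disjoint item pairs, given θ,
  latent bivariate normals with correlation ρ (default 0.50) are thresholded
  against the conditional response probabilities.  Since Φ(v) is uniform,
  every univariate conditional margin is preserved exactly; only the
  within-pair association changes.  This sampling construction was chosen
  precisely because margin preservation is provable.

These generators emulate the study conditions — standard-normal traits, no
missing data, dichotomous items, misfit confined to known items or pairs.
They do not emulate features of real testing data such as guessing across
all items, multidimensionality, speededness or nonignorable omissions, so
passing calibration here demonstrates correctness of the statistics under
the stated conditions, not robustness to everything real data can do.

## Scenario harness

Presets bundle the benchmark simulation designs: the 20-item 5×4 parameter crossing at
N = 1000 (`size-scenario-1`); test lengths 10/20/40 × sample sizes
250/1000/10000 with discriminations 0.8/1.2 over ten equally spaced
intercepts in [−1.5, 1.5] (`size-scenario-2` — for G = 10 the two
discriminations alternate over the ten intercepts, for G = 40 the crossed
20-item design is duplicated; the assignment is immaterial because rates are
item-averaged); and the power presets with four misfit items (ids 3, 8, 13,
18, spread over the difficulty range — the design is symmetric in which
items are chosen) or eight dependent pairs (1–2), (4–5), (6–7), (9–10),
(11–12), (14–15), (16–17), (19–20) at ρ = 0.50.

Each replication gets a pre-assigned child seed (NumPy `SeedSequence`
spawning), so tables are identical for any worker count and rerun.
Rejection uses the strict convention p < α (immaterial for continuous
p-values, fixed for reproducibility).  Replications whose fits fail are
excluded and counted; more than 10 % failures abort the scenario.
Infeasible tests (non-positive trace of Σ_d) are tallied and reported as
NaN p-values.

## Numerical and scale choices

* Monte-Carlo scales: the large-sample item-level null study runs at its
  full 250 replications.  The G = 20 global null study runs at 100
  replications with the bootstrap's B = 200 unchanged, and the power studies
  at 100 replications; the comparisons use binomial standard errors at the
  replication count actually run.
* Quadrature default of 21 nodes balances accuracy and speed; raising it
  changes fitted values well below sampling noise in all designs used here.
* EM tolerance 1e−6 on the log-likelihood, maximum 500 iterations; polish
  gradient tolerance 1e−7.  ULS gradient tolerance 1e−12.
* The expected information is enumerated exactly (2^20 patterns, chunked)
  in the null-calibration presets at G ≤ 20, where the reference
  distribution must be precise, and for G = 40 falls back to Monte Carlo.
  The power presets use seeded Monte-Carlo information with 10⁵ draws
  (relative error a few tenths of a percent): power rates are insensitive
  to sub-percent covariance noise, and exact enumeration at every
  replication would dominate their run time.
* Degenerate inputs: items with one response category, margins at 0/1,
  subset sizes outside 1–4 for joint probabilities, and non-disjoint copula
  pairs all raise typed errors early.

## Known limitations

* One-dimensional 2PL only; no polytomous items, no multidimensional
  extension, no missing-data handling.
* The analytic global test inherits the finite-sample liberality documented
  for it — at N = 1000 with 20 items its Type-I error sits above nominal
  (the bootstrap version is better calibrated); neither version is a remedy
  for small samples (N ≤ 250).
* The difference covariance may fail positive definiteness in finite
  samples; the package reports, rather than repairs, such cases.
* The alternative covariance constructions that guarantee positive
  semi-definiteness are not implemented.
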