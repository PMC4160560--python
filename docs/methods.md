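# Methods

## Model and estimands

All procedures assume the random-effects meta-regression model

    Y | X ~ N(Xβ, Δ + τ²I),    Δ = diag(σ_i²),

with n studies, a full-column-rank n×p design X (first column ones unless an
intercept-free fit is requested), and within-study variances σ_i² treated as
fixed and known. The estimand throughout is τ², the residual between-study
variance. At least p + 1 studies are required for identification; the
package warns (but does not refuse) below 10 studies for a single-covariate
meta-regression, where interval estimates become very wide.

The exactness statements below are *conditional on the model*: normality,
independence, known σ_i², linear covariate effects. With real data these are
approximations, so "exact" coverage should be read as "exact under the
model"; the simulation harness verifies the mathematics, not the model.

## Generalised Q intervals

For fixed positive weights a_i, Q_a = yᵀBy with
B = A − AX(XᵀAX)⁻¹XᵀA. The distribution of Q_a is a weighted sum of n − p
independent χ²₁ variables whose weights are the nonzero eigenvalues of
S = Σ^{1/2}BΣ^{1/2} (equivalently of (I − H)AΣ, H the hat matrix of the
A^{1/2}X regression); p eigenvalues vanish structurally. The eigenvalues are
non-decreasing in τ², hence the CDF of Q_a is decreasing in τ², and
inverting the equal-tailed test

    P(Q_a ≥ q_a; τ²) ≥ α/2   and   P(Q_a ≤ q_a; τ²) ≥ α/2

yields an interval. Only equal tail splits are implemented.

Weight choices: `conventional` (a_i = 1/σ_i², recovers the classical Q and
its χ²_{n−p} null), `inverse-sd` (a_i = 1/σ_i, suited when some
heterogeneity is anticipated), `total-variance` (a_i = 1/(σ_i² + τ̂²)) and
`custom`. The theory requires *fixed* weights; total-variance weights are
estimated and therefore only approximately valid — constructing them emits a
warning. No ranking of weight choices is implied by the package.

The moments estimator (q_obs − tr(BΔ))/tr(B) is unbiased before truncation
at zero; its standard error sqrt(Var(Q_a))/tr(B), with
Var(Q_a) = 2tr(BΔBΔ) + 4τ²tr(BΔB) + 2τ⁴tr(B²) evaluated at the truncated
estimate (a plug-in choice; a user-supplied τ² may replace it), is reported
as a descriptive measure only. No normal-approximation interval is built
from it: the distribution of Q_a is strongly right-skewed at meta-analytic
sample sizes.

## Weighted chi-square CDF

P(Σ λ_i χ²₁ ≤ q) is evaluated by Ruben's expansion in central chi-square
CDFs with scale β = min λ_i:

    P = Σ_k a_k P(χ²_{m+2k} ≤ q/β),

whose coefficients are non-negative and sum to one, so truncating after K
terms has error at most 1 − Σ_{k≤K} a_k. The series is summed until that
bound falls below 1e−8 (warning with the achieved bound if 20,000 terms are
reached first, which does not occur for the eigenvalue spreads arising
here). The chi-square CDFs are evaluated in one vectorised regularised
incomplete-gamma call. An Imhof-type characteristic-function inversion was
considered and rejected: its integrand decays like u^{−(m/2+1)}, too slowly
for reliable quadrature when the number of components m = n − p is very
small.

Eigenvalues below 1e−10 × λ_max are treated as the p structural zeros; a
deviation from exactly p such values raises an error rather than silently
proceeding.

## Interval root-finding

Both tail equations are solved by Brent's method on τ² with absolute
tolerance 1e−8, after doubling an upper bracket from 10·τ̂² + 1 until the
tail condition flips (cap 1e6; a cap hit raises an error naming the last
bracket). Monotonicity of the CDF in τ² guarantees a single sign change.

## Q-profile method

The pivot Q(τ²) = Σ (y_i − x_i β̂(τ²))²/(σ_i² + τ²), with β̂(τ²) the GLS fit
at that τ², follows χ²_{n−p} at the true τ². Its total derivative reduces to
−Σ r_i²/(σ_i² + τ²)² because the indirect dependence through β̂ vanishes at
the weighted-least-squares optimum (an envelope argument); the derivative is
therefore strictly negative away from perfect fit, Q is decreasing, and test
inversion gives an interval via three cases on Q(0) against the χ²_{n−p}
quantiles: below the lower quantile → degenerate/empty; between → [0, U];
above the upper quantile → [L, U].

Equations Q(τ²) = c are solved by Newton–Raphson with the update

    τ²_{k+1} = τ²_k + (Q(τ²_k) − c) / Σ r_i²/(σ_i² + τ²_k)²,

negative iterates replaced by zero, started at the truncated moments
estimate (or a caller-supplied value). Convergence: |Δτ²| < 1e−10 or
|Q − c| < 1e−8, cap 100 iterations; a non-convergent trajectory falls back
to safeguarded bisection, which monotonicity guarantees will succeed. The
Paule–Mandel estimate solves Q(τ²) = n − p (zero if Q(0) ≤ n − p), is
unique, equals the empirical Bayes estimator, and under the [0,0] convention
always lies inside the same-level Q-profile interval — a property the test
suite checks on hundreds of random instances.

## Degenerate-interval conventions

When even τ² = 0 is rejected from below, the accepted set is empty. The
default `zero-zero` convention reports [0, 0] — conservative, raising
coverage to 1 − α/2 at τ² = 0 — while the `empty` convention reports an
empty set, preserving the nominal coverage everywhere at the cost of
interpretability. `IntervalResult.contains` treats the empty set as
containing nothing, and [0, 0] as containing exactly zero, which is what
the coverage harness tallies.

## Bayesian analysis

The likelihood is the marginal model above (random effects integrated out).
Priors: independent uniforms on each β entry (default bounds ±10) and one of
four τ² families — log-normal on τ², log-t with 5 degrees of freedom on τ²
(informative choices such as logN(−1.83, 1.52²), logN(−2.56, 1.74²),
lt₅(−3.02, 2.27²), lt₅(−3.44, 2.59²) come from published prior elicitations
for between-study variances and are passed as parameters, not hard-coded),
or vague uniform/half-normal priors stated on τ. Priors on τ acquire the
Jacobian 1/(2τ) on the τ² scale; their hyperparameters default to upper = 10
and scale = 1 — package defaults, configurable per analysis.

Sampling is Metropolis-within-Gibbs on (β, log τ²):

* β given τ²: componentwise Gibbs with exact 1-D truncated-normal draws
  (inverse-CDF), whose stationary law is the conditional multivariate normal
  restricted to the prior box. This remains correct and fast however the box
  compares with the conditional spread (rejection sampling does not).
* log τ²: random-walk Metropolis, three refreshes per sweep (several cheap
  inner steps cut the autocorrelation of the slowest component), proposal
  scale adapted toward 44% acceptance during burn-in only and frozen
  afterwards, so the kept draws target the exact posterior.

Default plan: 3 chains, 10,000 burn-in, 200,000 kept draws per chain, with
chain starts at the moments estimate and the generalised-Q interval
endpoints; the test suite runs reduced plans (3 × 5,000) since only
distributional correctness is at stake at desk scale. Credible intervals
are the 2.5%/97.5% posterior quantiles.

Convergence is diagnosed by the Brooks–Gelman corrected potential scale
reduction factor, floored at 1 and flagged (warning plus `converged=False`,
never a silent return) above 1.05 — the threshold is a package choice. For
τ² the diagnostic is computed on log τ², the sampler's unconstrained
coordinate: a variance-ratio statistic is unstable on the heavy-tailed τ²
marginal and can exceed 1.1 for chains whose log-scale moments agree to
three decimals.

## Synthetic data and the coverage harness

`ScenarioSpec` draws datasets from the model itself: designs are
intercept-only, intercept + binary covariate (default six of sixteen studies
at level one, the shape of a two-dose-group meta-regression), or intercept +
uniform continuous covariate; within-study variances come from an explicit
list or uniform/log-uniform ranges, with log-uniform on [0.02, 0.5] as the
default — a realistic spread for log relative risks from small-to-moderate
trials. Covariates and σ_i² are realised once per scenario and held fixed
across replicates, because they are fixed known quantities in the model and
the exactness claim is conditional on them; a clearly-labelled off-model
mode redraws σ_i² per replicate for robustness exploration. Every replicate
seeds its own generator from (scenario seed, replicate index), so runs are
reproducible and replicates independent.

Because the generator *is* the model, passing coverage checks demonstrates
the mathematics of the intervals, not robustness to non-normal effects,
estimated σ_i², correlated outcomes or covariate error — all outside the
generator's scope. The harness reports per-method empirical coverage with
binomial standard errors, mean width of non-degenerate intervals, [0,0] and
empty-set rates, and counts (rather than propagates) per-replicate failures.

Problem sizes used by the checked-in studies: 2,000 replicates of n = 16,
p = 2 for the 95% coverage runs (binomial SE ≈ 0.5 points), 2,000 replicates
at τ² = 0 for the 97.5% truncated-coverage property, 500 random instances
for the structural invariants, and 3 × 5,000-draw chains for the MCMC
checks.

## Input handling

Study tables are CSV/TSV with named columns: either precomputed effect
sizes and variances, or 2×2 event counts per study, converted to log
relative risks with variance 1/a − 1/(a+b) + 1/c − 1/(c+d) (the standard
delta-method formula under the normal approximation). The 1/2 continuity
correction is added to all four cells of a table, by default only when that
table contains a zero cell; an always-correct mode exists for comparability
with software that corrects every table. Reading uses the round-trip float
parser so that writing and re-reading a dataset reproduces it bit-for-bit.
Rank-deficient designs raise an error naming the collinear columns.

## Known limitations

* Exactness is model-conditional; σ_i² are estimated in practice.
* No REML fitting and no profile-likelihood, Wald or bootstrap intervals.
* Effect sizes other than the log relative risk must be supplied
  precomputed; no clustered or multivariate outcomes.
* Total-variance weights break the fixed-weights assumption (warned, not
  forbidden).
* The MCMC sampler is a single-purpose Metropolis-within-Gibbs; for models
  beyond this likelihood use a general-purpose PPL.
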