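# Methods

## The cost model

An evaluation by `n` judges has expected total cost

    cost(n) = C_j · n + C_e · P_e(n)

with `C_j > 0` the cost per judge, `C_e > 0` the cost of a wrong decision,
and `P_e(n)` the probability the panel picks the worse of two options. The
*optimal* panel size is the argmin of this curve; dividing by `C_j` shows it
depends on the costs only through the ratio `r = C_e / C_j` (the exchange
identity, tested). Optimisation is an exact argmin over an explicit integer
range (default odd 1..51), not a derivative heuristic: panel sizes are
small, so exhaustive evaluation is both exact and cheap. Cost ties within a
relative tolerance of 1e-12 are reported together, with the smallest size
as the optimum, since fewer judges never cost more. `n = 0` is excluded —
an evaluation needs at least one judge.

The difference-quotient form of the optimality condition,
`C_j ≈ C_e · |ΔP_e/Δn|`, is *not* used for the forward search; it is the
basis of the inverse inference below, where it is exactly the statement
that `n_opt` beats its neighbouring panel sizes.

## Majority rule (analytic)

Judges are independent and honest but fallible; each picks the better of
two options with probability `p`. For an odd panel,

    P(n, p) = Σ_{k > n/2} C(n,k) p^k (1−p)^{n−k} = I_p((n+1)/2, (n+1)/2),

the upper binomial tail, equal to a regularized incomplete beta function.
Both forms are implemented (scipy's `binom.sf` and `betainc`) and agree to
1e-12 across the tested grid; the identity serves as an internal
cross-check. Panels are restricted to odd sizes — even panels are rejected
rather than tie-broken, keeping the analytic forms exact.

Mixed panels (counts `n₁, n₂` with accuracies `p₁, p₂`, odd total) convolve
the two binomial vote-count distributions and sum the strict-majority tail.
This is validated against exhaustive enumeration over all `2^(n₁+n₂)` vote
patterns for totals up to 11. The inferior-judge search (`min_added_judges`)
steps additions by two so the total stays odd.

Pairwise-majority analysis of rank profiles compares options two at a time;
ties yield no edge and a Condorcet winner must strictly beat every rival,
so "no clear winner" covers both cycles and ties.

## Scoring systems (Monte Carlo)

Judge `i`'s score for the worse option B is `N(m_i, (cv·m_i)²)` and for the
better option A is `N(c·m_i, (cv·c·m_i)²)`:

- `m_i` — the judge's personal scale, drawn per judge from a *mean-draw*
  distribution. Three regimes are built in: tight `normal(7, 0.7)`
  (skating-like score sheets), broad `lognormal(mean 700, sd 1400)`
  (microarray-probe-like intensities), and `normal(2, 0.5)` (grant
  prescores).
- `cv = 0.2` — coefficient of variation of a judge's own scores.
- `c > 1` — the separation constant, the multiplicative quality gap
  between the options.

Because both standard deviations scale with the judge's own mean, the
single-judge accuracy

    a(c, cv) = Φ((c−1) / (cv·√(1+c²)))

does not depend on `m_i`; `c = 1.1607` at `cv = 0.2` calibrates judges to
70%. Calibration inverts this closed form by squaring (a quadratic in `c`,
larger root), exact to the 1e-10 round-trip tested. Targets so high that
`(Φ⁻¹(a)·cv)² ≥ 1` are unreachable for any separation and raise an error.

Lognormal mean/sd are moments of the lognormal itself and are converted to
underlying-normal parameters via `σ² = ln(1+(sd/mean)²)`,
`μ = ln(mean) − σ²/2`; the conversion is verified on 10⁶ draws. Normal
mean-draws ≤ 0 are rejected and redrawn (for `normal(2, 0.5)` this affects
~3·10⁻⁵ of draws) so cv-scaled standard deviations stay positive.

Raw simulation draws 100,000 panels per data point by default, matching the
scale at which the accuracy-curve contrasts (sum vs majority at n = 9) are
clearly resolved; unit tests run 20,000–60,000 panels with 3-standard-error
tolerances. Per-size substreams are spawned from a single seed
(`numpy.random.SeedSequence.spawn`), so curves are reproducible point-wise
and adding sizes never perturbs existing points. Exact sum-rule ties,
possible only through floating-point coincidence, fall to a seeded fair
coin.

### Conditional (Rao-Blackwellized) error estimator

Conditional on the drawn means, the sum-rule score-total difference is
normal, so

    P(error | m) = Φ(−(c−1)·Σmᵢ / (cv·√(1+c²)·√(Σmᵢ²))).

Averaging this over mean draws estimates the sum-rule error with far lower
variance than scoring panels directly (the indicator is replaced by its
conditional expectation). The estimator is validated against raw Monte
Carlo with paired seeds. It is essential for the grant-review inversion,
where the decisive error-probability differences are ~5·10⁻⁵ — below raw-MC
resolution at 10⁵ panels.

## Inverse inference

At an optimal odd majority panel `n*`, beating both odd neighbours means

    2/(P(n*) − P(n*−2))  ≤  r  ≤  2/(P(n*+2) − P(n*)),

which inverts to the implied cost-ratio interval; scaling by `C_e` and
reversing gives the implied fee interval (the two are exact algebraic
transforms of the same accuracy increments, tested as an identity). For
`n* = 1` the interval is one-sided from zero. Currency and ratio endpoints
are reported with **ceiling** rounding — the convention under which all four
published-style endpoints (100, 152, 305, 2138) emerge from the unrounded
values (≈99.3, ≈151.2, ≈304.6, ≈2137.5); the raw endpoints are always kept
on the interval object. Intervals require `p > 0.5` so the accuracy curve
is strictly increasing.

### Implied judge accuracy (grant review)

Given `n_opt` sum-rule reviewers, `C_j` and `C_e`, the estimator sweeps the
separation constant over `c ∈ [1.05, 1.60]` in steps of 0.001 and keeps
values where the difference-quotient optimality condition holds on both
sides:

    C_e·(P_e(n_opt−1) − P_e(n_opt))   ≥  Δn·C_j
    C_e·(P_e(n_opt)   − P_e(n_opt+1)) ≤  Δn·C_j

with `Δn = 2` by default. Retaining the `Δn = 2` divisor of the odd-panel
majority-rule development — rather than switching to a plain cost
comparison across the one-step neighbours — is a deliberate design choice:
it treats the optimality condition as the same difference quotient
`|dP_e/dn| ≈ Δn⁻¹·ΔP_e ≈ C_j/C_e` throughout the package, and it is the
convention under which the grant-review accuracy ranges (87–89% and 67–69%
at `C_e` = $400k and $4k) are reproduced. `step=1` switches to the literal
cost comparison; the implied accuracies then come out 1.5–7 points higher,
because a marginal judge must repay a full fee over a single size step.

Error probabilities at `n_opt−1, n_opt, n_opt+1` use the conditional
estimator with **common random numbers**: one matrix of judge means
(100,000 panels × `n_opt+1` judges by default) is drawn once and reused for
every `c` and, through its leading columns, for every panel size, so the
tiny differences that decide the interval are estimated with strongly
positively correlated noise. 100,000 draws mirrors the panel budget used
throughout the scoring simulations; the rounded endpoints are stable across
seeds at this budget (tested over five seeds, and at the reduced 20,000
budget used by the faster unit tests).

The surviving `c` values can form **two disjoint bands** — `n_opt` is
locally optimal on both flanks of the single-peaked accuracy→optimal-size
profile (for mediocre judges the accuracy curve is still shallow; for good
judges it has flattened). The estimator reports the high-accuracy band by
default (`branch="upper"`), the regime these inverse analyses address; the
low band (near-chance judges) is available via `branch="lower"`. Band
edges are refined by root-solving the binding condition between grid points
(smooth deterministic functions of `c` once the means are frozen): the
high-cost lower endpoint sits ~0.02 percentage points from a
nearest-percent rounding boundary, so grid snapping alone could flip its
rounded value. Accuracy endpoints are reported in percent with
nearest-integer rounding. An empty surviving set (errors too cheap for
`n_opt` ever to be optimal) returns an explicit empty interval, not an
exception.

## Empirical estimators and synthetic fixtures

Two estimators read judge accuracy off contest records, both treating the
consensus as ground truth and hence giving upper bounds: the fraction of
judges whose *strictly* highest score went to the event's top competitor
(ties count against the judge — a judge who cannot single out the best has
failed to), and the fraction of per-bout picks agreeing with each bout's
majority (odd panels only). Both are invariant to row/column permutations
of the sheet.

The synthetic score-sheet generator extends the two-option model to K
competitors: each judge draws a base mean; competitor k's mean is the base
times the cumulative product of the first k quality gaps (each ≥ 1), so the
last listed competitor is the true best and the gap equal to the 70%
calibration constant reproduces a 0.70 per-judge top-score rate on two
competitors. Sheets are reproducible given a seed.

What the synthetic models do *not* emulate: inter-judge dependence
(discussion, deference, strategic scoring), per-judge heterogeneity in `cv`
or `c`, multi-stage review, more than two latent quality levels per
contest, and judge-specific costs. Tests passing under these models show
the calculus and its estimators are implemented correctly, not that real
panels satisfy the independence and equal-accuracy assumptions.

## Numerical and design notes

- Accuracies are probabilities throughout the library; the CLI accepts
  percentages (values above 1) and normalises.
- Binomial tails come from `scipy.stats.binom.sf`, the beta form from
  `scipy.special.betainc`, normal CDF/quantile from
  `scipy.special.ndtr/ndtri`; the mixed-panel convolution, cost calculus,
  conditional estimator and inversions are implemented here.
- Contour grids evaluate all odd sizes up to `n_max` (default 51) per grid
  cell; `argmin` takes the first minimiser, so ties already resolve toward
  smaller panels.
- The paradox scan reports every grid triple `(p_low, p_high, r)` with a
  larger optimum at the higher accuracy; on the default integer-ratio grid
  the 65%/70% reversal occupies several ratio ranges below 60 and none
  above, but the exact number of ranges depends on grid resolution and is
  checked qualitatively.
- Known limitation: `P(n, p)` saturates to 1.0 in double precision for
  large `n` and `p` near 1, where strict jury-theorem monotonicity becomes
  numerically vacuous; property tests avoid that regime.
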