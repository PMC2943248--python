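"""Inverse inference: what costs or accuracies are implied by a panel size
being optimal?

At an optimum of the expected cost C_j*n + C_e*P_e(n), a difference
approximation of the derivative gives the local-optimality condition

    C_j ~= C_e * |dP_e/dn|,

so a panel size n* that beats both of its neighbours pins the unknowns into
an interval.  Three inversions are provided:

* implied cost ratio r = C_e/C_j from (judge accuracy, n*) — e.g. nine
  figure-skating judges at 76% accuracy imply r in 100-152;
* implied per-judge fee from (judge accuracy, n*, C_e) — e.g. three boxing
  judges at 95% with a $100,000 purse imply a fee of $305-$2138;
* implied judge accuracy from (n*, C_j, C_e) under the grant-review sum-rule
  scoring model, by sweeping the separation constant c and keeping the
  values for which n* is locally cost-optimal.

Reported currency/ratio endpoints are rounded *up* to the next integer
(ceiling); accuracy endpoints are rounded to the nearest percent.  The raw
unrounded endpoints are always retained on the interval object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import special

from .cost import CostParams
from .scoring import MeanDrawSpec, judge_accuracy_from_separation
from .voting import majority_accuracy

__all__ = [
    "ImpliedInterval",
    "implied_cost_ratio_interval",
    "implied_judge_cost_interval",
    "implied_accuracy_interval",
]


@dataclass(frozen=True)
class ImpliedInterval:
    """An implied range for an unknown quantity, with its rounding convention.

    ``lower``/``upper`` are the raw endpoints; ``rounded()`` applies the
    recorded convention ("ceil" to the next integer for currencies and
    ratios, "nearest" integer for percentages, "none" to pass through).
    An empty interval (no value consistent with the constraints) is a normal
    result, flagged by ``is_empty``.
    """

    lower: float
    upper: float
    rounding: str = "none"
    units: str = ""
    is_empty: bool = False

    def __post_init__(self) -> None:
        if not self.is_empty and self.lower > self.upper:
            raise ValueError(f"lower {self.lower} exceeds upper {self.upper}")
        if self.rounding not in ("none", "ceil", "nearest"):
            raise ValueError(f"unknown rounding convention {self.rounding!r}")

    @classmethod
    def empty(cls, units: str = "") -> "ImpliedInterval":
        return cls(math.nan, math.nan, rounding="none", units=units, is_empty=True)

    def rounded(self) -> tuple[float, float]:
        if self.is_empty:
            return (math.nan, math.nan)
        if self.rounding == "ceil":
            return (float(math.ceil(self.lower)), float(math.ceil(self.upper)))
        if self.rounding == "nearest":
            return (float(round(self.lower)), float(round(self.upper)))
        return (self.lower, self.upper)


def _majority_increment(p: float, n_low: int, n_high: int) -> float:
    return majority_accuracy(p, n_high) - majority_accuracy(p, n_low)


def implied_cost_ratio_interval(p: float, n_opt: int) -> ImpliedInterval:
    """Cost ratios C_e/C_j for which an odd panel of ``n_opt`` judges with
    accuracy ``p`` beats both odd neighbours.

    n_opt beats n_opt-2 when r*(P(n_opt)-P(n_opt-2)) >= 2 and beats n_opt+2
    when r*(P(n_opt+2)-P(n_opt)) <= 2, so the interval is

        [ 2/(P(n_opt)-P(n_opt-2)),  2/(P(n_opt+2)-P(n_opt)) ].

    For n_opt = 1 only the upper comparison exists and the interval is
    one-sided from 0.  Requires p > 0.5 so the accuracy increments are
    positive.
    """
    if not 0.5 < p <= 1.0:
        raise ValueError("judge accuracy must exceed 0.5 for an increasing curve")
    if n_opt < 1 or n_opt % 2 == 0:
        raise ValueError("n_opt must be an odd integer >= 1")
    upper = 2.0 / _majority_increment(p, n_opt, n_opt + 2)
    if n_opt == 1:
        return ImpliedInterval(0.0, upper, rounding="ceil", units="cost ratio")
    lower = 2.0 / _majority_increment(p, n_opt - 2, n_opt)
    return ImpliedInterval(lower, upper, rounding="ceil", units="cost ratio")


def implied_judge_cost_interval(
    p: float, n_opt: int, cost_per_error: float
) -> ImpliedInterval:
    """Per-judge fees under which ``n_opt`` beats both odd neighbours, given
    the cost of an error.

    Algebraically the reciprocal of the cost-ratio inversion scaled by C_e:
    lower = C_e*(P(n_opt+2)-P(n_opt))/2 (fee low enough that stopping at
    n_opt is justified against adding two judges), upper =
    C_e*(P(n_opt)-P(n_opt-2))/2.
    """
    if cost_per_error <= 0:
        raise ValueError("cost_per_error must be positive")
    if not 0.5 < p <= 1.0:
        raise ValueError("judge accuracy must exceed 0.5 for an increasing curve")
    if n_opt < 3 or n_opt % 2 == 0:
        raise ValueError("n_opt must be an odd integer >= 3")
    lower = cost_per_error * _majority_increment(p, n_opt, n_opt + 2) / 2.0
    upper = cost_per_error * _majority_increment(p, n_opt - 2, n_opt) / 2.0
    return ImpliedInterval(lower, upper, rounding="ceil", units="currency per judge")


def implied_accuracy_interval(
    n_opt: int,
    costs: CostParams,
    *,
    mean_draw: MeanDrawSpec = MeanDrawSpec("normal", 2.0, 0.5),
    cv: float = 0.2,
    c_grid: Optional[Sequence[float]] = None,
    n_mean_draws: int = 100_000,
    seed: int = 0,
    step: int = 2,
    branch: str = "upper",
    refine: bool = True,
) -> ImpliedInterval:
    """Single-judge accuracies (percent) consistent with ``n_opt`` reviewers
    being locally optimal under the sum-rule scoring model.

    For each separation constant c on the grid, the sum-rule error
    probability at n_opt-1, n_opt, n_opt+1 is estimated with the conditional
    (Rao-Blackwellized) estimator: a single matrix of judge means is drawn
    once (``n_mean_draws`` panels of n_opt+1 judges) and reused for every c
    and, via its leading columns, for every panel size — common random
    numbers that make error-probability differences of order 1e-5
    resolvable.  A value of c survives when the difference-quotient
    optimality condition holds on both sides:

        C_e*(P_e(n_opt-1) - P_e(n_opt)) >= step*C_j
        C_e*(P_e(n_opt)   - P_e(n_opt+1)) <= step*C_j

    ``step`` is the divisor Delta-n of the difference quotient
    |dP_e/dn| ~ C_j/C_e at the optimum.  The default 2 keeps the convention
    of the odd-panel majority-rule analysis (where neighbouring panel sizes
    are two apart) and is the convention under which the published
    grant-review accuracy ranges are reproduced; ``step=1`` gives the plain
    expected-cost comparison against the two adjacent sizes.

    The surviving c values can form two disjoint bands, one on each side of
    the single peak of the optimal-size profile: a panel of n_opt judges is
    locally optimal both for rather inaccurate judges (the accuracy curve is
    still shallow) and for good-but-imperfect judges (the curve has begun to
    flatten).  ``branch`` selects which band to report: "upper" (default)
    takes the most accurate band, the regime the inverse analyses address;
    "lower" takes the least accurate one.  With ``refine=True`` the band
    edges are sharpened by root-solving the binding condition between grid
    points (the conditions are smooth deterministic functions of c once the
    judge means are frozen).

    The default grid sweeps c from 1.05 to 1.60 in steps of 0.001.  Returns
    an empty interval if no c qualifies (e.g. errors so cheap that a single
    judge always wins).
    """
    if n_opt < 2:
        raise ValueError("n_opt must be >= 2 so both neighbours exist")
    if branch not in ("upper", "lower"):
        raise ValueError("branch must be 'upper' or 'lower'")
    if step < 1:
        raise ValueError("step must be a positive integer")
    if c_grid is None:
        c_grid = np.linspace(1.05, 1.60, 551)
    c_grid = np.asarray(c_grid, dtype=float)
    if (c_grid <= 1.0).any():
        raise ValueError("all separation values must exceed 1")

    rng = np.random.default_rng(seed)
    means = mean_draw.sample(rng, (n_mean_draws, n_opt + 1))

    # conditional error depends on the means only through sum(m)/sqrt(sum(m^2))
    ratios = {}
    for n in (n_opt - 1, n_opt, n_opt + 1):
        m = means[:, :n]
        ratios[n] = m.sum(axis=1) / np.sqrt((m * m).sum(axis=1))

    def error_prob(c: float, n: int) -> float:
        z = (c - 1.0) / (cv * math.sqrt(1.0 + c * c))
        return float(special.ndtr(-z * ratios[n]).mean())

    threshold = step * costs.cost_per_judge / costs.cost_per_error

    def slack(c: float) -> float:
        """Positive iff both optimality conditions hold at c."""
        gain_in = error_prob(c, n_opt - 1) - error_prob(c, n_opt)
        gain_out = error_prob(c, n_opt) - error_prob(c, n_opt + 1)
        return min(gain_in - threshold, threshold - gain_out)

    pe = {}
    k = (c_grid - 1.0) / (cv * np.sqrt(1.0 + c_grid * c_grid))  # (C,)
    for n in (n_opt - 1, n_opt, n_opt + 1):
        vals = np.empty(c_grid.size)
        for start in range(0, c_grid.size, 64):  # chunked to bound memory
            block = k[start : start + 64]
            vals[start : start + 64] = special.ndtr(
                -block[:, None] * ratios[n][None, :]
            ).mean(axis=1)
        pe[n] = vals
    ok = (pe[n_opt - 1] - pe[n_opt] >= threshold) & (
        pe[n_opt] - pe[n_opt + 1] <= threshold
    )
    idx = np.nonzero(ok)[0]
    if idx.size == 0:
        return ImpliedInterval.empty(units="% accuracy")
    components = np.split(idx, np.nonzero(np.diff(idx) > 1)[0] + 1)
    comp = components[-1] if branch == "upper" else components[0]
    c_lo = float(c_grid[comp[0]])
    c_hi = float(c_grid[comp[-1]])

    if refine:
        from scipy import optimize

        i0, i1 = int(comp[0]), int(comp[-1])
        if i0 > 0 and slack(c_grid[i0 - 1]) < 0 < slack(c_lo):
            c_lo = float(optimize.brentq(slack, c_grid[i0 - 1], c_lo, xtol=1e-8))
        if i1 < c_grid.size - 1 and slack(c_grid[i1 + 1]) < 0 < slack(c_hi):
            c_hi = float(optimize.brentq(slack, c_hi, c_grid[i1 + 1], xtol=1e-8))

    return ImpliedInterval(
        100.0 * judge_accuracy_from_separation(c_lo, cv),
        100.0 * judge_accuracy_from_separation(c_hi, cv),
        rounding="nearest",
        units="% accuracy",
    )
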