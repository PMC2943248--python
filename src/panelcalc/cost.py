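"""Expected-cost curves over panel size, optimal-panel search, and the
more-accurate-judges paradox.

The expected total cost of an evaluation by n judges is

    cost(n) = C_j * n + C_e * P_e(n)

with C_j the cost per judge, C_e the cost of a wrong decision and P_e(n) the
panel's error probability.  The optimal panel size minimises this cost; only
the ratio r = C_e / C_j matters for the argmin.  Counter-intuitively, the
optimal size is not monotone in judge accuracy: over a range of cost ratios
a panel of 70%-accurate judges has a *larger* optimum than a panel of
65%-accurate judges, because the more accurate panel's accuracy curve is
steeper where the marginal judge still pays for itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence, Union

import numpy as np
from scipy import stats

from .scoring import AccuracyCurveEstimate
from .voting import majority_accuracy

__all__ = [
    "CostParams",
    "CostCurve",
    "OptimalPanel",
    "majority_curve",
    "expected_cost_curve",
    "optimal_panel",
    "optimal_panel_contour",
    "find_paradox_pairs",
]

AccuracyLike = Union[Mapping[int, float], Callable[[int], float], AccuracyCurveEstimate]


@dataclass(frozen=True)
class CostParams:
    """Cost per judge C_j and cost per error C_e (both positive)."""

    cost_per_judge: float
    cost_per_error: float

    def __post_init__(self) -> None:
        if self.cost_per_judge <= 0 or self.cost_per_error <= 0:
            raise ValueError("both costs must be positive")

    @property
    def ratio(self) -> float:
        """r = C_e / C_j, the only combination the optimal size depends on."""
        return self.cost_per_error / self.cost_per_judge


@dataclass(frozen=True)
class CostCurve:
    points: dict[int, float]
    params: CostParams

    def cost(self, n: int) -> float:
        return self.points[n]


@dataclass(frozen=True)
class OptimalPanel:
    """Argmin of a cost curve; ties (within relative tolerance) go to the
    smallest panel, and every tied size is reported."""

    n_opt: int
    min_cost: float
    all_minima: tuple[int, ...]


def majority_curve(p: float, n_values: Iterable[int]) -> dict[int, float]:
    """Analytic majority-rule accuracy curve n -> P(n, p) over odd sizes."""
    return {n: majority_accuracy(p, n) for n in n_values}


def _accuracy_at(acc: AccuracyLike, n: int) -> float:
    if isinstance(acc, AccuracyCurveEstimate):
        if n not in acc.points:
            raise KeyError(f"accuracy curve has no point at n={n}")
        return acc.accuracy(n)
    if callable(acc):
        return float(acc(n))
    if n not in acc:
        raise KeyError(f"accuracy curve has no point at n={n}")
    return float(acc[n])


def expected_cost_curve(
    acc: AccuracyLike, costs: CostParams, n_range: Sequence[int]
) -> CostCurve:
    """Evaluate cost(n) = C_j*n + C_e*(1 - accuracy(n)) over ``n_range``."""
    if len(n_range) == 0:
        raise ValueError("n_range is empty")
    points = {
        int(n): costs.cost_per_judge * n
        + costs.cost_per_error * (1.0 - _accuracy_at(acc, n))
        for n in n_range
    }
    return CostCurve(points=points, params=costs)


def optimal_panel(
    acc: AccuracyLike,
    costs: CostParams,
    n_range: Sequence[int],
    rel_tol: float = 1e-12,
) -> OptimalPanel:
    """Exact argmin of the expected cost over an explicit integer range.

    ``n_range`` should hold odd sizes for analytic majority curves.  Sizes
    whose cost is within ``rel_tol`` (relative) of the minimum count as tied
    minima; the smallest wins since fewer judges never cost more.
    """
    curve = expected_cost_curve(acc, costs, n_range)
    ns = sorted(curve.points)
    values = np.array([curve.points[n] for n in ns])
    best = float(values.min())
    tied = tuple(n for n, v in zip(ns, values) if v <= best * (1.0 + rel_tol))
    return OptimalPanel(n_opt=tied[0], min_cost=best, all_minima=tied)


def optimal_panel_contour(
    p_grid: Sequence[float], r_grid: Sequence[float], n_max: int = 51
) -> np.ndarray:
    """Optimal odd panel size for analytic majority rule on a grid of judge
    accuracies (rows) and cost ratios (columns), with C_j = 1.

    Vectorised: for each accuracy the full odd-n cost matrix over all ratios
    is built at once; ``argmin`` returns the first (smallest) minimiser.
    """
    p_grid = np.asarray(p_grid, dtype=float)
    r_grid = np.asarray(r_grid, dtype=float)
    if n_max < 1 or n_max % 2 == 0:
        raise ValueError("n_max must be odd")
    ns = np.arange(1, n_max + 1, 2)
    out = np.empty((p_grid.size, r_grid.size), dtype=int)
    for i, p in enumerate(p_grid):
        acc = stats.binom.sf(ns // 2, ns, p)
        cost = ns[:, None] + r_grid[None, :] * (1.0 - acc[:, None])
        out[i] = ns[np.argmin(cost, axis=0)]
    return out


def find_paradox_pairs(
    contour: np.ndarray, p_grid: Sequence[float], r_grid: Sequence[float]
) -> list[tuple[float, float, float]]:
    """All grid triples (p_low, p_high, r) with p_low < p_high but a larger
    optimal panel at the *higher* accuracy — the paradox cases."""
    p_grid = np.asarray(p_grid, dtype=float)
    r_grid = np.asarray(r_grid, dtype=float)
    pairs: list[tuple[float, float, float]] = []
    for j, r in enumerate(r_grid):
        col = contour[:, j]
        for i_low in range(p_grid.size):
            for i_high in range(i_low + 1, p_grid.size):
                if col[i_high] > col[i_low]:
                    pairs.append((float(p_grid[i_low]), float(p_grid[i_high]), float(r)))
    return pairs
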