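"""Analytic accuracy of majority-rule panels and pairwise-majority analysis.

A *panel* is a committee of independent judges choosing between two options,
one of which is objectively better.  Each judge picks the better option with
some probability (the judge's *accuracy*); under majority rule the option
favoured by more judges wins.  Panels are kept odd so no vote ties occur.

For a uniform panel of ``n`` judges with accuracy ``p`` the panel accuracy is
the upper binomial tail

    P(n, p) = sum_{k > n/2} C(n, k) p^k (1 - p)^(n - k),

equivalently the regularized incomplete beta function
``I_p((n+1)/2, (n+1)/2)``.  The Condorcet Jury Theorem follows: for
``p > 1/2`` the panel accuracy increases monotonically with ``n``.

Mixed panels (two blocks of judges with different accuracies) are handled by
convolving the two binomial vote-count distributions, which shows that adding
judges *worse* than the incumbents can lower the panel accuracy for a long
stretch before the jury theorem reasserts itself.

This module also provides pairwise-majority ("Condorcet") analysis of rank
profiles: comparing options two at a time by majority vote yields a directed
graph which may contain cycles (the Voter's paradox) and hence no clear
winner.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "PanelGroup",
    "PanelComposition",
    "RankProfile",
    "PairwiseDigraph",
    "majority_accuracy",
    "majority_accuracy_beta",
    "mixed_panel_accuracy",
    "min_added_judges",
    "pairwise_majority",
    "condorcet_winner",
]


@dataclass(frozen=True)
class PanelGroup:
    """A block of identically accurate judges.

    Parameters
    ----------
    count
        Number of judges in the block (non-negative).
    accuracy
        Probability in [0, 1] that a single judge picks the better option.
    """

    count: int
    accuracy: float

    def __post_init__(self) -> None:
        if self.count < 0 or int(self.count) != self.count:
            raise ValueError(f"count must be a non-negative integer, got {self.count}")
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError(f"accuracy must lie in [0, 1], got {self.accuracy}")


@dataclass(frozen=True)
class PanelComposition:
    """A possibly mixed panel, described as a sequence of judge blocks."""

    groups: tuple[PanelGroup, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        if self.total_count < 1:
            raise ValueError("a panel needs at least one judge")

    @property
    def total_count(self) -> int:
        return sum(g.count for g in self.groups)


def _check_odd(n: int, what: str = "panel size") -> None:
    if n < 1 or n % 2 == 0:
        raise ValueError(f"{what} must be an odd integer >= 1, got {n}")


def majority_accuracy(p: float, n: int) -> float:
    """Probability that an odd panel of ``n`` judges, each with accuracy ``p``,
    reaches the correct majority decision.

    Examples
    --------
    >>> round(majority_accuracy(0.8, 3), 3)
    0.896
    """
    _check_odd(n)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"accuracy must lie in [0, 1], got {p}")
    # tail P(X >= (n+1)/2) for X ~ Binomial(n, p)
    return float(stats.binom.sf(n // 2, n, p))


def majority_accuracy_beta(p: float, n: int) -> float:
    """Same quantity via the regularized incomplete beta function
    ``I_p((n+1)/2, (n+1)/2)`` — an exact analytic identity used as a
    cross-check on the binomial tail."""
    _check_odd(n)
    k = (n + 1) // 2
    return float(special.betainc(k, k, p))


def mixed_panel_accuracy(group1: PanelGroup, group2: PanelGroup) -> float:
    """Majority accuracy of a panel mixing two blocks of judges.

    The number of correct votes is the sum of two independent binomials;
    their distributions are convolved and the upper tail (strict majority of
    the combined panel) summed.  The total panel size must be odd.
    """
    n = group1.count + group2.count
    _check_odd(n, "total panel size")
    pmf1 = stats.binom.pmf(np.arange(group1.count + 1), group1.count, group1.accuracy)
    pmf2 = stats.binom.pmf(np.arange(group2.count + 1), group2.count, group2.accuracy)
    total = np.convolve(pmf1, pmf2)
    return float(total[n // 2 + 1 :].sum())


def composition_accuracy(panel: PanelComposition) -> float:
    """Majority accuracy of an arbitrary mixed panel (any number of blocks)."""
    n = panel.total_count
    _check_odd(n, "total panel size")
    dist = np.array([1.0])
    for g in panel.groups:
        pmf = stats.binom.pmf(np.arange(g.count + 1), g.count, g.accuracy)
        dist = np.convolve(dist, pmf)
    return float(dist[n // 2 + 1 :].sum())


def min_added_judges(
    base: PanelGroup, added_accuracy: float, max_added: int = 100
) -> Optional[int]:
    """Smallest even number of extra judges of accuracy ``added_accuracy``
    whose addition raises the mixed-panel accuracy strictly above the base
    panel's own majority accuracy.

    Judges are added two at a time so the total stays odd.  Returns ``None``
    if no addition up to ``max_added`` helps (inferior judges may depress the
    panel accuracy for a long stretch — e.g. a 3-judge panel at 80% needs 22
    judges at 60% before the mixture beats the original 89.6%).
    """
    _check_odd(base.count, "base panel size")
    baseline = majority_accuracy(base.accuracy, base.count)
    for m in range(2, max_added + 1, 2):
        if mixed_panel_accuracy(base, PanelGroup(m, added_accuracy)) > baseline:
            return m
    return None


# ---------------------------------------------------------------------------
# Pairwise-majority (Condorcet) analysis of rank profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankProfile:
    """Rankings of K options by J judges.

    ``ranks[j, k]`` is judge j's rank for option k; each row must be a
    permutation of 1..K with 1 = most preferred.
    """

    options: tuple[str, ...]
    ranks: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "options", tuple(str(o) for o in self.options))
        ranks = np.asarray(self.ranks, dtype=int)
        object.__setattr__(self, "ranks", ranks)
        if ranks.ndim != 2 or ranks.shape[1] != len(self.options):
            raise ValueError("ranks must be a judges x options matrix")
        expected = np.arange(1, len(self.options) + 1)
        for j, row in enumerate(ranks):
            if not np.array_equal(np.sort(row), expected):
                raise ValueError(
                    f"row {j} is not a permutation of 1..{len(self.options)}: {row}"
                )

    @property
    def n_judges(self) -> int:
        return self.ranks.shape[0]

    @classmethod
    def from_csv(cls, path) -> "RankProfile":
        """Read a rank profile from CSV: header row of option names, one row
        of integer ranks per judge."""
        df = pd.read_csv(path)
        if df.empty:
            raise ValueError(f"no judge rows in {path}")
        return cls(options=tuple(df.columns), ranks=df.to_numpy())


@dataclass(frozen=True)
class PairwiseDigraph:
    """Majority tournament over options.

    ``edges`` holds ordered (winner, loser) pairs; ``tie_pairs`` holds
    unordered pairs where the judges split evenly.  Every unordered option
    pair appears exactly once, either as an edge or as a tie.
    """

    options: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    tie_pairs: frozenset[frozenset[str]]

    def beats(self, a: str, b: str) -> bool:
        return (a, b) in self.edges


def pairwise_majority(profile: RankProfile) -> PairwiseDigraph:
    """Compare options two at a time by majority preference.

    For each option pair, the option ranked better (lower rank number) by
    strictly more judges gets a directed edge to the other; even splits are
    recorded as ties.
    """
    opts = profile.options
    edges: set[tuple[str, str]] = set()
    ties: set[frozenset[str]] = set()
    for i, j in itertools.combinations(range(len(opts)), 2):
        prefer_i = int(np.sum(profile.ranks[:, i] < profile.ranks[:, j]))
        prefer_j = profile.n_judges - prefer_i
        if prefer_i > prefer_j:
            edges.add((opts[i], opts[j]))
        elif prefer_j > prefer_i:
            edges.add((opts[j], opts[i]))
        else:
            ties.add(frozenset((opts[i], opts[j])))
    return PairwiseDigraph(options=opts, edges=frozenset(edges), tie_pairs=frozenset(ties))


def condorcet_winner(digraph: PairwiseDigraph) -> Optional[str]:
    """The option that strictly beats every rival, or ``None`` if a cycle or
    tie prevents a clear winner (Voter's paradox)."""
    for opt in digraph.options:
        if all(digraph.beats(opt, other) for other in digraph.options if other != opt):
            return opt
    return None
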