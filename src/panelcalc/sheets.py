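"""Score-sheet I/O, empirical judge-accuracy estimators, and synthetic
score-sheet generation.

Two empirical estimators mirror how judge accuracy is read off real contest
records: the fraction of judges whose strictly highest score went to the
stage's top competitor (scoring systems, e.g. figure skating), and the
fraction of per-bout picks agreeing with the bout's majority decision
(vote-style contests, e.g. boxing).  Both treat the consensus choice as
ground truth, so they are upper bounds on true accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .scoring import ScoringModel

__all__ = [
    "ScoreSheet",
    "read_score_sheet",
    "write_score_sheet",
    "estimate_accuracy_top_score",
    "estimate_accuracy_majority_agreement",
    "generate_fixture_scoresheet",
]


@dataclass(frozen=True)
class ScoreSheet:
    """Judges x competitors matrix of numeric scores."""

    judge_ids: tuple[str, ...]
    competitor_ids: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "judge_ids", tuple(str(j) for j in self.judge_ids))
        object.__setattr__(
            self, "competitor_ids", tuple(str(c) for c in self.competitor_ids)
        )
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.shape != (len(self.judge_ids), len(self.competitor_ids)):
            raise ValueError(
                f"score matrix shape {scores.shape} does not match "
                f"{len(self.judge_ids)} judges x {len(self.competitor_ids)} competitors"
            )
        if len(set(self.judge_ids)) != len(self.judge_ids):
            raise ValueError("duplicate judge ids")
        if len(set(self.competitor_ids)) != len(self.competitor_ids):
            raise ValueError("duplicate competitor ids")
        if np.isnan(scores).any():
            rows, cols = np.nonzero(np.isnan(scores))
            raise ValueError(
                f"missing/non-numeric score at judge {self.judge_ids[rows[0]]!r}, "
                f"competitor {self.competitor_ids[cols[0]]!r}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=list(self.judge_ids), columns=list(self.competitor_ids)
        )


def read_score_sheet(path) -> ScoreSheet:
    """Read a CSV score sheet: header of competitor ids, first column judge
    ids, numeric body.  Malformed cells are reported with their location."""
    df = pd.read_csv(path, index_col=0)
    if df.empty:
        raise ValueError(f"score sheet {path} has no judge rows")
    body = df.apply(pd.to_numeric, errors="coerce")
    return ScoreSheet(
        judge_ids=tuple(str(i) for i in df.index),
        competitor_ids=tuple(str(c) for c in df.columns),
        scores=body.to_numpy(),
    )


def write_score_sheet(sheet: ScoreSheet, path) -> None:
    sheet.to_frame().to_csv(path, index_label="judge")


def estimate_accuracy_top_score(sheet: ScoreSheet, best_competitor: str) -> float:
    """Fraction of judges whose strictly highest score went to
    ``best_competitor``.  A judge tying the top two counts as a failure
    (the judge failed to single out the best)."""
    if best_competitor not in sheet.competitor_ids:
        raise ValueError(f"unknown competitor {best_competitor!r}")
    col = sheet.competitor_ids.index(best_competitor)
    best_score = sheet.scores[:, col]
    others = np.delete(sheet.scores, col, axis=1)
    hits = (best_score[:, None] > others).all(axis=1)
    return float(hits.mean())


def estimate_accuracy_majority_agreement(bouts: Sequence[Sequence[str]]) -> float:
    """Over all (bout, judge) pairs, the fraction of picks agreeing with the
    bout's majority pick.  Each bout is a sequence of per-judge winner picks
    and must have an odd number of judges (no vote ties)."""
    if len(bouts) == 0:
        raise ValueError("no bouts provided")
    agree = 0
    total = 0
    for i, picks in enumerate(bouts):
        picks = list(picks)
        if len(picks) % 2 == 0 or len(picks) == 0:
            raise ValueError(f"bout {i} has an even panel ({len(picks)} picks)")
        if len(set(picks)) > 2:
            raise ValueError(f"bout {i} names more than two options")
        winner = max(set(picks), key=picks.count)
        agree += sum(1 for p in picks if p == winner)
        total += len(picks)
    return agree / total


def generate_fixture_scoresheet(
    model: ScoringModel,
    n_judges: int,
    n_competitors: int,
    quality_gaps: Sequence[float],
    seed: int,
) -> ScoreSheet:
    """Synthetic score sheet with a known ground-truth ranking.

    Extends the two-option scoring model to K competitors: each judge draws a
    base mean from the model's mean-draw distribution; competitor k's mean
    for that judge is the base mean times the product of the first k quality
    gaps (each gap >= 1), so the *last* listed competitor is the true best.
    Scores are then normal with sd = cv * mean.  Reproducible given the seed.
    """
    if n_competitors < 2:
        raise ValueError("need at least two competitors")
    if len(quality_gaps) != n_competitors - 1:
        raise ValueError(
            f"expected {n_competitors - 1} quality gaps, got {len(quality_gaps)}"
        )
    gaps = np.asarray(quality_gaps, dtype=float)
    if (gaps < 1.0).any():
        raise ValueError("quality gaps must each be >= 1")
    rng = np.random.default_rng(seed)
    base = model.mean_draw.sample(rng, n_judges)  # (J,)
    factors = np.concatenate([[1.0], np.cumprod(gaps)])  # (K,)
    means = base[:, None] * factors[None, :]
    scores = rng.normal(means, model.cv * means)
    return ScoreSheet(
        judge_ids=tuple(f"J{i + 1}" for i in range(n_judges)),
        competitor_ids=tuple(f"C{i + 1}" for i in range(n_competitors)),
        scores=scores,
    )
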