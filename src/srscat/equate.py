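"""Equipercentile equating and POMP rescaling.

Places short-form raw scores (0-48) on the full-scale raw metric (0-195) by
matching continuized percentile ranks: integer scores are treated as the
intervals [x-0.5, x+0.5) of a piecewise-linear (uniform-kernel) cumulative
distribution, and each source score maps to the target-scale value with the
same percentile rank.  Percent-of-maximum-possible (POMP) rescaling is the
secondary, distribution-free method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SrsCatError

__all__ = [
    "ScoreDistribution",
    "ConcordanceTable",
    "percentile_rank",
    "equipercentile_equate",
    "pomp_scale",
]


@dataclass(frozen=True)
class ScoreDistribution:
    """Integer-score frequency distribution on [scale_min, scale_max]."""

    scale_min: int
    scale_max: int
    frequencies: np.ndarray  # length scale_max - scale_min + 1

    def __post_init__(self):
        freq = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", freq)
        if self.scale_max < self.scale_min:
            raise SrsCatError("scale_max must be >= scale_min")
        if freq.shape != (self.scale_max - self.scale_min + 1,):
            raise SrsCatError("frequencies must cover every integer score")
        if np.any(freq < 0) or freq.sum() <= 0:
            raise SrsCatError("frequencies must be non-negative with positive total")

    @classmethod
    def from_scores(cls, scores, scale_min: int, scale_max: int) -> "ScoreDistribution":
        scores = np.asarray(scores)
        if scores.size == 0:
            raise SrsCatError("cannot build a distribution from zero scores")
        rounded = np.rint(scores).astype(int)
        if rounded.min() < scale_min or rounded.max() > scale_max:
            raise SrsCatError(
                f"scores outside scale [{scale_min}, {scale_max}]: "
                f"observed [{rounded.min()}, {rounded.max()}]"
            )
        freq = np.bincount(rounded - scale_min, minlength=scale_max - scale_min + 1)
        return cls(scale_min, scale_max, freq.astype(float))

    @property
    def total(self) -> float:
        return float(self.frequencies.sum())

    @property
    def scores(self) -> np.ndarray:
        return np.arange(self.scale_min, self.scale_max + 1)


@dataclass(frozen=True)
class ConcordanceTable:
    """Source-score -> equated-target-score map, monotone non-decreasing."""

    source_scores: np.ndarray
    equated_scores: np.ndarray
    percentile_ranks: np.ndarray

    def lookup(self, scores) -> np.ndarray | float:
        """Equated value(s) for integer source score(s)."""
        scores = np.asarray(scores)
        idx = np.rint(scores).astype(int) - int(self.source_scores[0])
        if np.any(idx < 0) or np.any(idx >= len(self.source_scores)):
            raise SrsCatError("score outside the concordance table's source scale")
        out = self.equated_scores[idx]
        return float(out) if out.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source_score": self.source_scores,
                "equated_score": self.equated_scores,
                "percentile_rank": self.percentile_ranks,
            }
        )


def percentile_rank(score: int, dist: ScoreDistribution) -> float:
    """Mid-percentile rank: 100 * (count below + half the count at) / total."""
    score = int(score)
    if score < dist.scale_min or score > dist.scale_max:
        raise SrsCatError(
            f"score {score} outside scale [{dist.scale_min}, {dist.scale_max}]"
        )
    idx = score - dist.scale_min
    below = dist.frequencies[:idx].sum()
    at = dist.frequencies[idx]
    return float(100.0 * (below + 0.5 * at) / dist.total)


def _continuized_inverse_knots(dist: ScoreDistribution):
    """Knots (p, x) of the continuized CDF prepared for inversion.

    The CDF rises linearly over each score interval [x-0.5, x+0.5].  Flat runs
    (zero-frequency cells) are collapsed to the midpoint of the run so the
    inverse is single-valued; interior zero cells thereby inherit linearly
    interpolated cumulative values.
    """
    edges = dist.scale_min + np.arange(len(dist.frequencies) + 1) - 0.5
    cdf = np.concatenate([[0.0], np.cumsum(dist.frequencies) / dist.total])
    ps, xs = [], []
    i = 0
    while i < len(cdf):
        j = i
        while j + 1 < len(cdf) and cdf[j + 1] == cdf[i]:
            j += 1
        ps.append(cdf[i])
        xs.append(float(np.mean(edges[i : j + 1])))
        i = j + 1
    return np.array(ps), np.array(xs)


def equipercentile_equate(
    source: ScoreDistribution, target: ScoreDistribution
) -> ConcordanceTable:
    """Equipercentile concordance from the source scale to the target scale.

    For every integer source score the continuized target CDF is inverted at
    the source score's mid-percentile rank; equated values are clipped to the
    target scale.  A one-point target degenerates to a constant map (warned).
    """
    src_scores = source.scores
    ranks = np.array([percentile_rank(s, source) for s in src_scores])
    if np.count_nonzero(target.frequencies) == 1:
        point = float(target.scores[np.argmax(target.frequencies > 0)])
        warnings.warn(
            "target distribution is concentrated on a single score; "
            "all source scores map to it",
            stacklevel=2,
        )
        equated = np.full(len(src_scores), point)
    else:
        ps, xs = _continuized_inverse_knots(target)
        equated = np.interp(ranks / 100.0, ps, xs)
        equated = np.clip(equated, target.scale_min, target.scale_max)
    equated = np.maximum.accumulate(equated)  # guard monotonicity against fp jitter
    return ConcordanceTable(
        source_scores=src_scores, equated_scores=equated, percentile_ranks=ranks
    )


def pomp_scale(score, scale_min: float, scale_max: float):
    """Percent of maximum possible: 100 * (score - min) / (max - min)."""
    if scale_max <= scale_min:
        raise SrsCatError("scale_max must exceed scale_min")
    arr = np.asarray(score, dtype=float)
    if np.any(arr < scale_min) or np.any(arr > scale_max):
        raise SrsCatError(
            f"score outside scale [{scale_min}, {scale_max}]"
        )
    out = 100.0 * (arr - scale_min) / (scale_max - scale_min)
    return float(out) if out.ndim == 0 else out
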