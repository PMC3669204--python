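"""Evaluation statistics: ROC/AUC, threshold indices, confidence bins,
randomization Z-scores and score-reference correlation.

Conventions: a pair is predicted positive when its score is >= the
threshold; the ROC sweep visits the descending unique scores plus one
sentinel above the maximum so the curve spans (0,0) to (1,1); AUC is the
trapezoidal sum over consecutive (FPR, TPR) points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import DegenerateInputError

POSITIVE, NEGATIVE = 1, 0


@dataclass(frozen=True)
class LabeledScore:
    pair: str
    score: float
    label: int  # 1 positive, 0 negative

    def __post_init__(self):
        if not math.isfinite(self.score):
            raise ValueError(f"non-finite score for pair {self.pair!r}")
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be 0/1, got {self.label!r}")


@dataclass(frozen=True)
class Confusion:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn)

    @property
    def ppv(self) -> Optional[float]:
        d = self.tp + self.fp
        return None if d == 0 else self.tp / d

    @property
    def npv(self) -> Optional[float]:
        d = self.tn + self.fn
        return None if d == 0 else self.tn / d


@dataclass
class RocCurve:
    points: list[Confusion]
    auc: float

    @property
    def thresholds(self) -> list[float]:
        return [p.threshold for p in self.points]


def _split(scores: Sequence[LabeledScore]) -> tuple[np.ndarray, np.ndarray]:
    pos = np.array([s.score for s in scores if s.label == POSITIVE], dtype=float)
    neg = np.array([s.score for s in scores if s.label == NEGATIVE], dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise DegenerateInputError("need at least one positive and one negative")
    return pos, neg


def confusion_at(scores: Sequence[LabeledScore], threshold: float) -> Confusion:
    """Confusion counts with the predict-positive-iff-score>=t rule."""
    pos, neg = _split(scores)
    tp = int((pos >= threshold).sum())
    fp = int((neg >= threshold).sum())
    return Confusion(threshold, tp=tp, fp=fp, tn=neg.size - fp, fn=pos.size - tp)


def roc_curve(scores: Sequence[LabeledScore]) -> RocCurve:
    """ROC over the descending unique scores plus a sentinel above the max."""
    pos, neg = _split(scores)
    uniq = np.unique(np.concatenate([pos, neg]))[::-1]
    thresholds = np.concatenate([[uniq[0] + 1.0], uniq])
    points = []
    for t in thresholds:
        tp = int((pos >= t).sum())
        fp = int((neg >= t).sum())
        points.append(Confusion(float(t), tp=tp, fp=fp, tn=neg.size - fp, fn=pos.size - tp))
    xs = np.array([p.fpr for p in points])
    ys = np.array([p.tpr for p in points])
    auc = float(np.sum((xs[1:] - xs[:-1]) * (ys[1:] + ys[:-1]) / 2.0))
    return RocCurve(points=points, auc=auc)


def youden_index(curve: RocCurve) -> tuple[float, float]:
    """(threshold, Y) maximizing Y = TPR - FPR; ties take the smallest
    threshold."""
    best_t, best_y = None, -math.inf
    for p in curve.points:
        y = p.tpr - p.fpr
        if y > best_y or (y == best_y and p.threshold < best_t):
            best_t, best_y = p.threshold, y
    return best_t, best_y


def f1_at(scores: Sequence[LabeledScore], threshold: float) -> Optional[float]:
    """F = 2 (PPV * TPR) / (PPV + TPR); None when undefined."""
    c = confusion_at(scores, threshold)
    if c.ppv is None or c.ppv + c.tpr == 0.0:
        return None
    return 2.0 * c.ppv * c.tpr / (c.ppv + c.tpr)


def best_f1(scores: Sequence[LabeledScore]) -> tuple[float, float]:
    """(threshold, F1) over the ROC threshold sweep; ties take the smallest
    threshold with a defined F1."""
    curve = roc_curve(scores)
    best_t, best_f = None, -math.inf
    for t in curve.thresholds:
        f = f1_at(scores, t)
        if f is None:
            continue
        if f > best_f or (f == best_f and t < best_t):
            best_t, best_f = t, f
    if best_t is None:
        raise DegenerateInputError("F1 undefined at every threshold")
    return best_t, best_f


# -- confidence binning ----------------------------------------------------

CONFIDENCE_LABELS = ("L", "M_L", "M_H", "H")


@dataclass(frozen=True)
class ConfidenceScheme:
    """Four left-closed bins over [0, 1]; the top bin is closed on both
    ends."""

    name: str
    cuts: tuple[float, float, float]  # L/M_L, M_L/M_H, M_H/H boundaries

    def __post_init__(self):
        c1, c2, c3 = self.cuts
        if not (0.0 < c1 < c2 < c3 <= 1.0):
            raise ValueError(f"cut points must be strictly increasing in (0, 1]: {self.cuts}")

    def intervals(self) -> tuple[str, str, str, str]:
        c1, c2, c3 = (_fmt(c) for c in self.cuts)
        return (f"[0, {c1})", f"[{c1}, {c2})", f"[{c2}, {c3})", f"[{c3}, 1]")


def _fmt(x: float) -> str:
    return f"{x:g}"


#: Built-in schemes for the hybrid-measure (MAX) score on PPI data.
BUILTIN_SCHEMES: dict[str, ConfidenceScheme] = {
    "yeast-bp": ConfidenceScheme("yeast-bp", (0.1, 0.2, 0.7)),
    "yeast-cc": ConfidenceScheme("yeast-cc", (0.1, 0.2, 0.5)),
    "human-bp": ConfidenceScheme("human-bp", (0.1, 0.2, 0.6)),
    "human-cc": ConfidenceScheme("human-cc", (0.1, 0.2, 0.5)),
}


def confidence_bin(score: float, scheme: ConfidenceScheme) -> str:
    """Map a score in [0, 1] to L / M_L / M_H / H."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score!r} outside [0, 1]")
    c1, c2, c3 = scheme.cuts
    if score < c1:
        return "L"
    if score < c2:
        return "M_L"
    if score < c3:
        return "M_H"
    return "H"


# -- randomization Z-score -------------------------------------------------


@dataclass(frozen=True)
class ZScoreReport:
    asv_observed: float
    reps: int
    null_mean: float
    null_stdev: float
    z: float
    seed: Optional[int]
    n_pairs: int
    n_dropped: int


def zscore_orthologs(
    pairs: Sequence[tuple[str, str]],
    scorer: Callable[[str, str], Optional[float]],
    reps: int = 1000,
    seed: Optional[int] = None,
) -> ZScoreReport:
    """Standardized deviation of the observed mean pair score from a
    permutation null.

    Each replicate re-pairs the first-column genes with a uniformly random
    bijection onto the second-column genes (true pairings are not
    excluded). ``scorer`` may return None for undefined pairs; those are
    dropped from the mean and counted.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if len(pairs) < 2:
        raise DegenerateInputError("need at least 2 pairs")
    rng = np.random.default_rng(seed)
    a_col = [a for a, _ in pairs]
    b_col = [b for _, b in pairs]

    cache: dict[tuple[str, str], Optional[float]] = {}

    def score(a: str, b: str) -> Optional[float]:
        key = (a, b)
        if key not in cache:
            cache[key] = scorer(a, b)
        return cache[key]

    def asv(bs: Sequence[str]) -> tuple[Optional[float], int]:
        vals = [v for v in (score(a, b) for a, b in zip(a_col, bs)) if v is not None]
        if not vals:
            return None, len(a_col)
        return float(np.mean(vals)), len(a_col) - len(vals)

    observed, dropped = asv(b_col)
    if observed is None:
        raise DegenerateInputError("no observed pair has a defined score")

    nulls = np.empty(reps, dtype=float)
    for r in range(reps):
        perm = rng.permutation(len(b_col))
        val, _ = asv([b_col[i] for i in perm])
        if val is None:
            raise DegenerateInputError("a randomized replicate has no defined scores")
        nulls[r] = val
    mean = float(nulls.mean())
    stdev = float(nulls.std(ddof=1)) if reps > 1 else 0.0
    # guard against pure summation noise masquerading as spread
    if stdev <= 1e-12 * max(1.0, abs(mean)):
        raise DegenerateInputError("null distribution has zero spread")
    return ZScoreReport(
        asv_observed=observed,
        reps=reps,
        null_mean=mean,
        null_stdev=stdev,
        z=(observed - mean) / stdev,
        seed=seed,
        n_pairs=len(pairs),
        n_dropped=dropped,
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Product-moment correlation; None when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors of size >= 3")
    if x.std() == 0.0 or y.std() == 0.0:
        return None
    return float(np.corrcoef(x, y)[0, 1])
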