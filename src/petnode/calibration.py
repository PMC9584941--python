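"""Operating-point calibration and (nested) cross-validation.

A classifier's sensitivity is adjusted in two ways: by raising the case
weight of positive nodes during training (weight calibration, at a fixed
probability cut-off of 0.5), and by lowering the probability cut-off at
or above which a node is called positive (cut-off calibration).  Out-of-
fold scores come from threefold cross-validation; for backends with an
inner model-selection step, nested cross-validation subdivides each outer
training set into five random samples, trains one candidate per left-out
sample, and picks the candidate with the highest sensitivity (then
highest specificity) on its own training data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "OperatingPoint",
    "FoldAssignment",
    "CalibrationError",
    "cutoff_for_sensitivity",
    "weight_for_sensitivity",
    "assign_folds",
    "nested_cv_scores",
    "cv_scores",
]

logger = logging.getLogger(__name__)


class CalibrationError(RuntimeError):
    """No grid value reached the target; carries the best achieved value."""

    def __init__(self, message: str, best_achieved: float):
        super().__init__(message)
        self.best_achieved = best_achieved


@dataclass(frozen=True)
class OperatingPoint:
    """A (weight, cut-off) pair fixing a classifier's sensitivity."""

    target_sensitivity: float
    positive_weight: float
    cutoff: float
    achieved_sensitivity: float
    achieved_specificity: float


@dataclass(frozen=True)
class FoldAssignment:
    """Outer fold id per record plus, per outer fold, inner sample ids.

    ``outer`` has values in 1..k.  ``inner`` is an (n, k) array whose
    column j-1 assigns an inner sample id in 1..m to every record outside
    outer fold j (0 for records inside fold j).
    """

    outer: np.ndarray
    inner: np.ndarray
    k: int
    m: int
    seed: int


def _sens_spec(scores, labels, cutoff):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    calls = scores >= cutoff
    pos = labels == 1
    sens = float(calls[pos].mean()) if pos.any() else float("nan")
    spec = float((~calls[~pos]).mean()) if (~pos).any() else float("nan")
    return sens, spec


def cutoff_for_sensitivity(scores: Sequence[float], labels: Sequence[int],
                           target: float) -> float:
    """Largest observed score c such that calling score >= c positive has
    sensitivity >= target.

    Sensitivity is non-decreasing as the cut-off decreases, so the answer
    is the k-th largest positive score with k = ceil(target * n_pos).
    """
    if not (0.0 < target <= 1.0):
        raise ValueError("target sensitivity must be in (0, 1]")
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos_scores = np.sort(scores[labels == 1])[::-1]
    if pos_scores.size == 0:
        raise ValueError("need at least one positive label")
    k = int(np.ceil(target * pos_scores.size))
    return float(pos_scores[k - 1])


def weight_for_sensitivity(
    trainer: Callable[[float], np.ndarray],
    labels: Sequence[int],
    target: float,
    cutoff: float = 0.5,
    weight_grid: Sequence[float] | None = None,
) -> OperatingPoint:
    """Smallest grid weight whose cross-validated sensitivity at the fixed
    cut-off reaches the target.

    ``trainer(w)`` must return per-record cross-validated scores of the
    classifier trained with positive-case weight ``w``.  The default grid
    is the integers 1..20.
    """
    if not (0.0 < target <= 1.0):
        raise ValueError("target sensitivity must be in (0, 1]")
    grid = sorted(weight_grid) if weight_grid is not None else list(range(1, 21))
    labels = np.asarray(labels, int)
    best = -np.inf
    for w in grid:
        scores = np.asarray(trainer(w), float)
        sens, spec = _sens_spec(scores, labels, cutoff)
        best = max(best, sens)
        if sens >= target:
            return OperatingPoint(
                target_sensitivity=target, positive_weight=float(w),
                cutoff=cutoff, achieved_sensitivity=sens,
                achieved_specificity=spec,
            )
    raise CalibrationError(
        f"no grid weight reached sensitivity {target}; best achieved {best:.4f}",
        best_achieved=best,
    )


def assign_folds(n: int, k: int = 3, m: int = 5, seed: int = 0) -> FoldAssignment:
    """Random outer folds of near-equal size and uniform inner samples.

    Outer folds are formed by sorting random keys into k consecutive
    blocks whose sizes differ by at most one.  Inner sample ids are
    independent uniform draws over 1..m (inner sizes are therefore
    random); an outer training set with an empty inner sample is redrawn
    with an incremented sub-seed and the event is logged.
    """
    if n < k * m:
        raise ValueError("need n >= k*m records")
    rng = np.random.default_rng(seed)
    keys = rng.random(n)
    order = np.argsort(keys, kind="stable")
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    outer = np.empty(n, dtype=int)
    start = 0
    for j in range(k):
        outer[order[start:start + sizes[j]]] = j + 1
        start += sizes[j]

    inner = np.zeros((n, k), dtype=int)
    for j in range(1, k + 1):
        mask = outer != j
        sub_seed = seed
        for attempt in range(100):
            draw_rng = np.random.default_rng(
                np.random.SeedSequence([seed, j, sub_seed + attempt])
            )
            ids = draw_rng.integers(1, m + 1, size=int(mask.sum()))
            if len(np.unique(ids)) == m:
                break
            logger.info(
                "outer fold %d: empty inner sample, re-randomising (attempt %d)",
                j, attempt + 1,
            )
        inner[mask, j - 1] = ids
    return FoldAssignment(outer=outer, inner=inner, k=k, m=m, seed=seed)


def nested_cv_scores(
    trainer: Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]],
    X: np.ndarray,
    y: Sequence[int],
    assignment: FoldAssignment,
    inner_cutoff: float = 0.5,
) -> np.ndarray:
    """Out-of-fold scores with the inner winner-selection rule.

    For each outer fold, m candidate models are trained, each on all but
    one inner sample of the outer training set; each candidate is ranked
    by (sensitivity, specificity) on its own training data at the inner
    cut-off, ties broken by lowest inner-sample id, and the winner scores
    the held-out fold.  Every record receives exactly one score from a
    model that never saw it.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    scores = np.empty(len(y), dtype=float)
    for j in range(1, assignment.k + 1):
        test_mask = assignment.outer == j
        train_mask = ~test_mask
        best_key = None
        best_model = None
        for s in range(1, assignment.m + 1):
            cand_mask = train_mask & (assignment.inner[:, j - 1] != s)
            model = trainer(X[cand_mask], y[cand_mask])
            sens, spec = _sens_spec(model(X[cand_mask]), y[cand_mask], inner_cutoff)
            key = (-(sens if np.isfinite(sens) else -1.0),
                   -(spec if np.isfinite(spec) else -1.0), s)
            if best_key is None or key < best_key:
                best_key, best_model = key, model
        scores[test_mask] = best_model(X[test_mask])
    return scores


def cv_scores(
    trainer: Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]],
    X: np.ndarray,
    y: Sequence[int],
    assignment: FoldAssignment,
) -> np.ndarray:
    """Plain k-fold out-of-fold scores (no inner selection)."""
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    scores = np.empty(len(y), dtype=float)
    for j in range(1, assignment.k + 1):
        test_mask = assignment.outer == j
        model = trainer(X[~test_mask], y[~test_mask])
        scores[test_mask] = model(X[test_mask])
    return scores
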