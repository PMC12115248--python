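"""Optimized rounding of continuous ordinal predictions to clinical grades.

A regression grader outputs a real number per recording; grading requires
an integer 1..4.  Plain rounding at (1.5, 2.5, 3.5) ignores how the model's
continuous outputs actually distribute, so the C−1 = 3 cut points are
instead fitted on out-of-fold validation predictions by maximizing an
agreement objective (Cohen's kappa by default, plain accuracy selectable)
with Nelder–Mead search over the cut vector.  Candidate cuts are sorted
before evaluation, which enforces monotonicity without constraints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

__all__ = ["ThresholdSet", "DEFAULT_CUTS", "apply_thresholds", "fit_thresholds"]

DEFAULT_CUTS: tuple[float, ...] = (1.5, 2.5, 3.5)

def _fast_accuracy(y: np.ndarray, yhat: np.ndarray) -> float:
    return float(np.mean(y == yhat))


def _fast_kappa(y: np.ndarray, yhat: np.ndarray) -> float:
    """Cohen's kappa over grades 1..4 (agrees with sklearn; cheap enough
    for the thousands of evaluations the threshold search makes)."""
    n = y.size
    cm = np.zeros((4, 4))
    np.add.at(cm, (y - 1, yhat - 1), 1.0)
    po = np.trace(cm) / n
    pe = float(cm.sum(axis=1) @ cm.sum(axis=0)) / (n * n)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


_OBJECTIVES = {
    "cohen_kappa": _fast_kappa,
    "accuracy": _fast_accuracy,
}


@dataclass(frozen=True)
class ThresholdSet:
    """C−1 strictly increasing cut points mapping reals to grades 1..C."""

    cuts: tuple[float, ...]
    objective_name: str = "unspecified"
    objective_value_at_fit: float | None = None

    def __post_init__(self) -> None:
        cuts = tuple(float(c) for c in self.cuts)
        object.__setattr__(self, "cuts", cuts)
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError(f"cuts must be strictly increasing: {cuts}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "cuts": list(self.cuts),
                    "objective_name": self.objective_name,
                    "objective_value_at_fit": self.objective_value_at_fit,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdSet":
        d = json.loads(Path(path).read_text())
        return cls(
            cuts=tuple(d["cuts"]),
            objective_name=d.get("objective_name", "unspecified"),
            objective_value_at_fit=d.get("objective_value_at_fit"),
        )


def apply_thresholds(
    preds: np.ndarray, cuts: ThresholdSet | tuple[float, ...] = DEFAULT_CUTS
) -> np.ndarray:
    """Map continuous predictions to grades: 1 + #cuts strictly below.

    A prediction exactly at a cut takes the lower grade (strict
    comparison); the map is monotone in the prediction.
    """
    if isinstance(cuts, ThresholdSet):
        cuts = cuts.cuts
    preds = np.asarray(preds, dtype=float)
    grades = np.ones(preds.shape, dtype=int)
    for c in cuts:
        grades += (preds > c).astype(int)
    return grades


def _objective_at(cuts: np.ndarray, preds, labels, objective_fn) -> float:
    rounded = apply_thresholds(preds, tuple(np.sort(cuts)))
    return objective_fn(labels, rounded)


def _coordinate_refine(cuts, preds, labels, objective_fn):
    """Snap each cut in turn to its best data midpoint, to convergence.

    The objective is piecewise constant with breakpoints only at the data
    values, so scanning midpoints between consecutive sorted predictions
    visits every achievable level for one cut given the others.  This
    deterministic pass pulls a Nelder–Mead iterate off its plateau.
    """
    s = np.sort(np.unique(preds))
    candidates = np.concatenate(
        [[s[0] - 1.0], (s[:-1] + s[1:]) / 2.0, [s[-1] + 1.0]]
    )
    cuts = np.sort(np.asarray(cuts, dtype=float))
    best = _objective_at(cuts, preds, labels, objective_fn)
    k = cuts.size
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    improved = True
    while improved:
        improved = False
        for i in range(k):
            for c in candidates:
                trial = cuts.copy()
                trial[i] = c
                val = _objective_at(trial, preds, labels, objective_fn)
                if val > best + 1e-12:
                    best, cuts = val, np.sort(trial)
                    improved = True
        # joint moves of two cuts escape ridges single-cut sweeps cannot
        for i, j in pairs:
            for ci in candidates:
                trial = cuts.copy()
                trial[i] = ci
                for cj in candidates:
                    t2 = trial.copy()
                    t2[j] = cj
                    v = _objective_at(t2, preds, labels, objective_fn)
                    if v > best + 1e-12:
                        best, cuts = v, np.sort(t2)
                        improved = True
    return cuts, best


def fit_thresholds(
    preds: np.ndarray,
    labels: np.ndarray,
    objective: str = "cohen_kappa",
    init: tuple[float, ...] = DEFAULT_CUTS,
    n_restarts: int = 4,
    seed: int = 0,
) -> ThresholdSet:
    """Fit cut points maximizing ``objective`` by Nelder–Mead search.

    The objective is piecewise constant in the cuts, so a single simplex
    can stall on a plateau; the search therefore restarts from the default
    cuts, from data-quantile cuts and from seeded random perturbations,
    refines each Nelder–Mead iterate by a deterministic coordinate snap to
    data midpoints, and keeps the best.  The fitted objective value never
    falls below the value at ``init``.
    """
    preds = np.asarray(preds, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if labels.size and not np.isin(labels, [1, 2, 3, 4]).all():
        raise ValueError("labels must be grades in 1..4")
    if preds.size != labels.size:
        raise ValueError("preds and labels differ in length")
    n_classes = len(init) + 1
    if preds.size < n_classes:
        raise ValueError(f"need at least {n_classes} points to fit cuts")
    if np.unique(labels).size < 2:
        raise ValueError("labels cover a single class; thresholds undefined")
    objective_fn = _OBJECTIVES[objective]

    rng = np.random.default_rng(seed)
    lo, hi = preds.min(), preds.max()
    span = max(hi - lo, 1e-6)
    starts = [np.asarray(init, dtype=float)]
    # quantile-based start adapts to the actual prediction distribution
    qs = np.quantile(preds, np.linspace(0, 1, n_classes + 1)[1:-1])
    starts.append(np.sort(qs) + np.linspace(0, 1e-6, n_classes - 1))
    for _ in range(n_restarts):
        starts.append(np.sort(lo + span * rng.random(n_classes - 1)))

    best_cuts = np.sort(np.asarray(init, dtype=float))
    best_val = _objective_at(best_cuts, preds, labels, objective_fn)
    for x0 in starts:
        res = minimize(
            lambda c: -_objective_at(c, preds, labels, objective_fn),
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-9, "maxiter": 400},
        )
        cuts, val = _coordinate_refine(res.x, preds, labels, objective_fn)
        if val > best_val + 1e-12:
            best_val = val
            best_cuts = cuts
    # break exact ties between cuts introduced by sorting equal coordinates
    for i in range(1, best_cuts.size):
        if best_cuts[i] <= best_cuts[i - 1]:
            best_cuts[i] = best_cuts[i - 1] + 1e-9
    return ThresholdSet(
        cuts=tuple(best_cuts),
        objective_name=objective,
        objective_value_at_fit=float(best_val),
    )
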