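"""Scoring new samples and survival-probability prediction.

The final linear predictor of a fitted hierarchy is the sum of the per-block
contributions (full-data coefficients), and for survival outcomes individual
curves are S(t | x) = exp(-H0(t) * exp(score)) with H0 the Breslow cumulative
baseline hazard estimated on the training data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataValidationError, DegenerateOutcomeError, FeatureMismatchError
from .io import SparseLinearModel


def _resolve_matrix(model, X) -> np.ndarray:
    feats = list(model.feature_names)
    if isinstance(X, pd.DataFrame):
        missing = [f for f in feats if f not in X.columns]
        if missing:
            raise FeatureMismatchError(f"matrix lacks model features: {missing[:5]}")
        return X[feats].to_numpy(float)
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[1] != len(feats):
        raise FeatureMismatchError(
            f"matrix has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"model expects {len(feats)}"
        )
    return X


def linear_score(model, X) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Full linear predictor and its per-block decomposition.

    ``X`` may be a DataFrame (columns matched by name) or an ndarray whose
    columns follow the model's feature order. The per-block contributions,
    plus the model intercept, sum exactly to the total score.
    """
    Xm = _resolve_matrix(model, X)
    contributions: dict[str, np.ndarray] = {}
    total = np.full(Xm.shape[0], model.intercept, dtype=float)
    col = 0
    for sf in model.step_fits:
        p = len(sf.features)
        contrib = Xm[:, col : col + p] @ sf.coef
        contributions[sf.block_name] = contrib
        total += contrib
        col += p
    return total, contributions


@dataclass(frozen=True)
class BaselineHazard:
    """Breslow cumulative baseline hazard: a nondecreasing step function."""

    times: np.ndarray  # sorted unique event times
    cumhaz: np.ndarray  # cumulative hazard at those times

    def __post_init__(self):
        t = np.asarray(self.times, float)
        h = np.asarray(self.cumhaz, float)
        if t.shape != h.shape or t.ndim != 1:
            raise DataValidationError("times and cumhaz must be 1-d, same length")
        if np.any(np.diff(t) <= 0):
            raise DataValidationError("event times must be strictly increasing")
        if (h < 0).any() or np.any(np.diff(h) < 0):
            raise DataValidationError("cumulative hazard must be nonnegative, nondecreasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "cumhaz", h)

    def at(self, eval_times) -> np.ndarray:
        """Right-continuous step evaluation: value at the latest jump <= t."""
        eval_times = np.asarray(eval_times, float)
        idx = np.searchsorted(self.times, eval_times, side="right") - 1
        out = np.where(idx >= 0, self.cumhaz[np.maximum(idx, 0)], 0.0)
        return out


def breslow_baseline(time, status, scores) -> BaselineHazard:
    """Breslow estimator: dH0(t) = d(t) / sum_{at risk at t} exp(score).

    With all scores zero this reduces to the Nelson-Aalen estimator. Tied
    event times share one increment (Breslow tie handling).
    """
    time = np.asarray(time, float)
    status = np.asarray(status)
    scores = np.asarray(scores, float)
    if status.sum() == 0:
        raise DegenerateOutcomeError("no events: baseline hazard undefined")
    order = np.argsort(time, kind="stable")
    t, s, sc = time[order], status[order], scores[order]
    ee = np.exp(sc - sc.max())
    rcum = np.cumsum(ee[::-1])[::-1]
    new = np.empty(len(t), bool)
    new[0] = True
    new[1:] = t[1:] != t[:-1]
    first = np.flatnonzero(new)
    grp = np.cumsum(new) - 1
    d = np.bincount(grp, weights=s.astype(float))
    rsum = rcum[first] * np.exp(sc.max())  # undo the stabilising shift
    ev = d > 0
    times = t[first][ev]
    increments = d[ev] / rsum[ev]
    return BaselineHazard(times, np.cumsum(increments))


def predict_survival(baseline: BaselineHazard, scores, eval_times) -> np.ndarray:
    """Predicted survival curves S(t | x) = exp(-H0(t) exp(score)).

    Returns an (n_samples, n_times) array; rows are nonincreasing in t and
    S(0) = 1 whenever no event precedes t = 0.
    """
    eval_times = np.asarray(eval_times, float)
    if (eval_times < 0).any():
        raise DataValidationError("evaluation times must be nonnegative")
    scores = np.asarray(scores, float)
    H = baseline.at(eval_times)
    return np.exp(-np.outer(np.exp(scores), H))


def average_survival(curves: np.ndarray, groups=None) -> dict:
    """Average predicted curves, overall or within risk groups."""
    if groups is None:
        return {"all": curves.mean(axis=0)}
    groups = np.asarray(groups)
    return {g: curves[groups == g].mean(axis=0) for g in pd.unique(groups)}
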