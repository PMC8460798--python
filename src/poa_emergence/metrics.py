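"""Fit statistics and Pearson screening of candidate predictors.

The three fit statistics reported for emergence models are the
coefficient of determination R² = 1 − SS_res/SS_tot, mean absolute error
MAE, and mean squared logarithmic error MSLE = mean (ln(1+y) − ln(1+ŷ))².
MSLE uses log1p — the standard definition — which requires every value to
exceed −1.

Predictor screening ranks candidate environmental series by the absolute
Pearson correlation of each with an emergence response (per-interval
increments by default; a cumulative-response mode exists behind a flag at
the pipeline level). Ranking only: no p-values and no multiple-testing
correction — this is an exploratory screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["r_squared", "mae", "msle", "pearson_screen", "ScreenResult"]


def _paired(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape[0]} observed vs {pred.shape[0]} predicted")
    return obs, pred


def r_squared(observed, predicted) -> float:
    """Coefficient of determination, 1 − SS_res/SS_tot.

    SS_tot is taken about the observed mean; the value can be negative for
    models worse than the mean. Undefined (raises) for a constant observed
    vector.
    """
    obs, pred = _paired(observed, predicted)
    if obs.size < 2:
        raise ValueError("r_squared requires at least 2 points")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("r_squared undefined for constant observed values")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def mae(observed, predicted) -> float:
    """Mean absolute error, mean |observed − predicted|."""
    obs, pred = _paired(observed, predicted)
    if obs.size == 0:
        raise ValueError("mae requires at least 1 point")
    return float(np.mean(np.abs(obs - pred)))


def msle(observed, predicted) -> float:
    """Mean squared logarithmic error, mean (log1p(obs) − log1p(pred))²."""
    obs, pred = _paired(observed, predicted)
    if obs.size == 0:
        raise ValueError("msle requires at least 1 point")
    if (obs <= -1).any() or (pred <= -1).any():
        raise ValueError("msle undefined for values ≤ −1")
    return float(np.mean((np.log1p(obs) - np.log1p(pred)) ** 2))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if denom == 0.0:
        return float("nan")
    return float(np.clip(np.sum(xc * yc) / denom, -1.0, 1.0))


@dataclass
class ScreenResult:
    """Pearson screening outcome: predictors ranked by |r| descending.

    ``ranking`` rows: (predictor_name, r, abs_r, defined). Zero-variance
    predictors have undefined r (NaN) and sort last with defined=False.
    """

    response_name: str
    ranking: pd.DataFrame

    @property
    def best(self) -> str:
        return str(self.ranking["predictor"].iloc[0])

    def r_of(self, name: str) -> float:
        row = self.ranking.loc[self.ranking["predictor"] == name, "r"]
        if row.empty:
            raise KeyError(f"no predictor named {name!r}")
        return float(row.iloc[0])

    def to_dict(self) -> dict:
        return {
            "response": self.response_name,
            "ranking": [
                {
                    "predictor": str(row.predictor),
                    "r": None if np.isnan(row.r) else float(row.r),
                    "abs_r": None if np.isnan(row.abs_r) else float(row.abs_r),
                    "defined": bool(row.defined),
                }
                for row in self.ranking.itertuples()
            ],
        }


def pearson_screen(
    predictors: pd.DataFrame | Mapping[str, Sequence[float]],
    response,
    response_name: str = "emergence_change",
) -> ScreenResult:
    """Rank candidate predictors by |Pearson r| against the response.

    ``predictors`` is wide-format: one named column per candidate series,
    all the same length as ``response`` (length ≥ 3). Constant predictors
    are reported as undefined and ranked last.
    """
    frame = pd.DataFrame(predictors)
    y = np.asarray(response, dtype=float).ravel()
    if len(frame) != len(y):
        raise ValueError(
            f"length mismatch: predictors have {len(frame)} rows, response {len(y)}"
        )
    if len(y) < 3:
        raise ValueError("screening requires at least 3 samples")
    rows = []
    for name in frame.columns:
        r = _pearson(frame[name].to_numpy(dtype=float), y)
        rows.append(
            {
                "predictor": str(name),
                "r": r,
                "abs_r": abs(r),
                "defined": not np.isnan(r),
            }
        )
    ranking = pd.DataFrame(rows)
    # NaNs (undefined) sort last; ties keep column order for determinism
    ranking = ranking.sort_values(
        ["defined", "abs_r"], ascending=[False, False], kind="stable"
    ).reset_index(drop=True)
    return ScreenResult(response_name=response_name, ranking=ranking)
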