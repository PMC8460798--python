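"""Non-linear emergence models: Gompertz and saturating exponential.

Two curve families map accumulated cooling degree days x to cumulative
emergence fraction y:

* Gompertz (early-season model):      y = a · exp(−b · exp(−c·x))
  a is the upper asymptote, b the x-displacement, c the rate. Inflection
  at x = ln(b)/c with value a/e.
* Saturating exponential (yearly-cumulative model, the feed-degradation
  "ruminal" form):                    y = −a + b · (1 − exp(−c·x))
  value −a at x = 0, asymptote −a + b, rate c.

Both are strictly increasing in x for positive b, c (and b > 0 for the
saturating form), so inverting for a target fraction — the thermal-time
benchmark at which, say, 50 % or 75 % of yearly emergence is predicted —
is a bracketed scalar root-find with a unique answer.

Emergence is a fraction in [0, 1] throughout; percent only at reporting.
Fitting is plain unweighted least squares with a deterministic multi-start
grid, via :func:`scipy.optimize.least_squares`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

from . import metrics as _metrics

__all__ = [
    "ModelKind",
    "ModelFit",
    "FitError",
    "gompertz_eval",
    "saturating_eval",
    "evaluate",
    "asymptote",
    "value_at_zero",
    "fit",
    "invert",
    "gompertz_inflection",
]

ModelKind = Literal["gompertz", "saturating_exp"]

#: Upper bound accepted for an emergence asymptote (fraction scale with
#: headroom for noisy fits).
_ASYMPTOTE_CAP = 1.5


def gompertz_eval(cdd, a: float, b: float, c: float):
    """Gompertz curve a·exp(−b·exp(−c·cdd)); vectorized over cdd."""
    cdd = np.asarray(cdd, dtype=float)
    out = a * np.exp(-b * np.exp(-c * cdd))
    return out.item() if out.ndim == 0 else out


def saturating_eval(cdd, a: float, b: float, c: float):
    """Saturating exponential −a + b·(1 − exp(−c·cdd)); vectorized."""
    cdd = np.asarray(cdd, dtype=float)
    out = -a + b * (1.0 - np.exp(-c * cdd))
    return out.item() if out.ndim == 0 else out


_EVALS = {"gompertz": gompertz_eval, "saturating_exp": saturating_eval}


def evaluate(kind: ModelKind, cdd, a: float, b: float, c: float):
    return _EVALS[kind](cdd, a, b, c)


def asymptote(kind: ModelKind, a: float, b: float, c: float) -> float:
    """Large-thermal-time limit of the model."""
    if kind == "gompertz":
        return float(a)
    if kind == "saturating_exp":
        return float(-a + b)
    raise ValueError(f"unknown model kind {kind!r}")


def value_at_zero(kind: ModelKind, a: float, b: float, c: float) -> float:
    if kind == "gompertz":
        return float(a * np.exp(-b))
    if kind == "saturating_exp":
        return float(-a)
    raise ValueError(f"unknown model kind {kind!r}")


def gompertz_inflection(b: float, c: float) -> float:
    """Thermal time of the Gompertz inflection point, ln(b)/c."""
    return float(np.log(b) / c)


@dataclass
class ModelFit:
    """A fitted (or externally supplied) emergence model.

    Parameter constraints enforced on construction: gompertz a ∈ (0, 1.5],
    b > 0, c > 0; saturating_exp c > 0 with asymptote −a + b ∈ (0, 1.5].
    """

    kind: ModelKind
    a: float
    b: float
    c: float
    n_points: int = 0
    converged: bool = True
    param_cov: np.ndarray | None = field(default=None, repr=False)
    r2: float | None = None
    mae: float | None = None
    msle: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "gompertz":
            if not (0 < self.a <= _ASYMPTOTE_CAP):
                raise ValueError(f"gompertz a must lie in (0, {_ASYMPTOTE_CAP}]")
            if self.b <= 0 or self.c <= 0:
                raise ValueError("gompertz b and c must be positive")
        elif self.kind == "saturating_exp":
            if self.c <= 0:
                raise ValueError("saturating_exp c must be positive")
            if not (0 < -self.a + self.b <= _ASYMPTOTE_CAP):
                raise ValueError(
                    f"saturating_exp asymptote −a+b must lie in (0, {_ASYMPTOTE_CAP}]"
                )
        else:
            raise ValueError(f"unknown model kind {self.kind!r}")

    @property
    def params(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def asymptote(self) -> float:
        return asymptote(self.kind, self.a, self.b, self.c)

    @property
    def value_at_zero(self) -> float:
        return value_at_zero(self.kind, self.a, self.b, self.c)

    def predict(self, cdd):
        return evaluate(self.kind, cdd, self.a, self.b, self.c)

    def benchmarks(self, targets: Sequence[float] = (0.5, 0.75)) -> dict[str, float]:
        """Thermal-time benchmarks, e.g. {'cdd_at_50': ..., 'cdd_at_75': ...}."""
        out = {}
        for t in targets:
            key = f"cdd_at_{round(t * 100)}"
            out[key] = invert(self, t)
        return out

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "params": {"a": self.a, "b": self.b, "c": self.c},
            "metrics": {"r2": self.r2, "mae": self.mae, "msle": self.msle},
            "n_points": self.n_points,
            "converged": self.converged,
        }
        return d


class FitError(RuntimeError):
    """Raised when no start converges; carries the best attempt found."""

    def __init__(self, message: str, best_params: tuple[float, float, float] | None = None):
        super().__init__(message)
        self.best_params = best_params


def _starts(kind: ModelKind, x: np.ndarray, y: np.ndarray):
    """Deterministic multi-start grid (fixed order, so fits reproduce)."""
    c_grid = (0.001, 0.01, 0.1)
    starts = []
    if kind == "gompertz":
        y_first = max(float(y[0]), 1e-6)
        for a0 in (0.5, 1.0):
            # log-displacement heuristic: choose b so the curve passes near
            # the first observation, clipped to a sane positive range
            b0 = float(np.clip(-np.log(min(y_first / a0, 1 - 1e-9)), 1e-3, 50.0))
            for c0 in c_grid:
                starts.append((a0, b0, c0))
    else:
        for b0 in (0.5, 1.0):
            for c0 in c_grid:
                starts.append((0.0, b0, c0))
    return starts


def _bounds(kind: ModelKind):
    if kind == "gompertz":
        return ([1e-9, 1e-9, 1e-9], [_ASYMPTOTE_CAP, 1e3, 10.0])
    return ([-_ASYMPTOTE_CAP, 1e-9, 1e-9], [_ASYMPTOTE_CAP, 2 * _ASYMPTOTE_CAP, 10.0])


def fit(
    points,
    kind: ModelKind,
    init: tuple[float, float, float] | None = None,
    bounds=None,
) -> ModelFit:
    """Least-squares fit of one model family to (cdd, fraction) points.

    ``points`` is anything unpackable into two equal-length vectors
    (a 2-column array, a (x, y) tuple, or an EmergenceCurve's
    ``.points()``). With ``init`` omitted, a deterministic grid of starts
    is tried and the lowest-cost convergent solution wins. Raises
    :class:`FitError` if no start converges (best attempt attached) and
    ``ValueError`` for unidentifiable input (constant response, too few
    points).
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2 and arr.shape[0] != 2:
        x, y = arr[:, 0], arr[:, 1]
    elif arr.ndim == 2 and arr.shape[0] == 2:
        x, y = arr[0], arr[1]
    else:
        raise ValueError("points must be two equal-length vectors of (cdd, fraction)")
    if len(x) < 4:
        raise ValueError("need at least 4 points to fit a 3-parameter model")
    if (x < 0).any():
        raise ValueError("cdd values must be non-negative")
    if np.ptp(x) == 0:
        raise ValueError("cdd values are all identical; model unidentifiable")
    if np.ptp(y) < 1e-12:
        raise ValueError("constant emergence fractions; model unidentifiable")

    lo, hi = bounds if bounds is not None else _bounds(kind)
    model = _EVALS[kind]

    def residuals(theta):
        return model(x, *theta) - y

    starts = [init] if init is not None else _starts(kind, x, y)
    best = None
    best_any = None
    for theta0 in starts:
        theta0 = np.clip(np.asarray(theta0, dtype=float), lo, hi)
        try:
            res = optimize.least_squares(
                residuals, theta0, bounds=(lo, hi), method="trf", max_nfev=2000
            )
        except Exception:  # pragma: no cover - scipy internal failure
            continue
        if best_any is None or res.cost < best_any.cost:
            best_any = res
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        bp = tuple(best_any.x) if best_any is not None else None
        raise FitError(f"no start converged for {kind} fit", best_params=bp)

    a, b, c = (float(v) for v in best.x)
    pred = model(x, a, b, c)
    cov = _param_cov(best, len(x))
    return ModelFit(
        kind=kind,
        a=a,
        b=b,
        c=c,
        n_points=len(x),
        converged=True,
        param_cov=cov,
        r2=_metrics.r_squared(y, pred) if np.ptp(y) > 0 else None,
        mae=_metrics.mae(y, pred),
        msle=_metrics.msle(y, pred) if (y > -1).all() and (pred > -1).all() else None,
    )


def _param_cov(res, n: int) -> np.ndarray | None:
    dof = n - len(res.x)
    if dof <= 0:
        return None
    J = res.jac
    try:
        jtj_inv = np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        return None
    s2 = 2.0 * res.cost / dof  # cost is 0.5·Σr²
    return jtj_inv * s2


def invert(fitobj: ModelFit, target: float) -> float:
    """Thermal time at which the model reaches ``target`` fraction.

    Bracketed root-finding (Brent) on the strictly monotone curve; the
    target must lie strictly between the model value at cdd = 0 and the
    asymptote, else a ValueError names the attainable range.
    """
    f0 = fitobj.value_at_zero
    asym = fitobj.asymptote
    if not (f0 < target < asym):
        raise ValueError(
            f"target {target} outside attainable range ({f0:.6g}, {asym:.6g}) "
            f"of the {fitobj.kind} model"
        )
    g = lambda x: fitobj.predict(x) - target
    hi = 100.0
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - unreachable for target < asymptote
            raise RuntimeError("failed to bracket the target")
    root = optimize.brentq(g, 0.0, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200)
    return float(root)
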