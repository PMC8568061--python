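"""Per-nucleus logarithmic min–max scaling of chemical shifts.

Backbone nuclei live on very different ppm scales (amide protons span
~2 ppm, amide nitrogens ~25 ppm), so shifts are mapped into a common
projection space before regression:

    f(x) = log_a((x - y_min) / (y_max - y_min) + 1) + theta

where ``y_min``/``y_max`` are the extrema of the *reference* (experimental)
shifts for that nucleus, ``a`` is the logarithm base (a hyperparameter in
[1.1, 10]) and ``theta`` is an additive offset tuned for the amide proton
only.  The map is strictly increasing, hence invertible, so regression
coefficients found in scaled space apply unchanged in ppm space.
"""

from __future__ import annotations

from typing import TYPE_CHECKING

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .io import NUCLEI, ShiftTable

if TYPE_CHECKING:  # pragma: no cover
    from .io import ShiftLibrary

#: Default bounds for the logarithm base.
A_BOUNDS: tuple[float, float] = (1.1, 10.0)
#: Default bounds for the amide-proton offset (scaled units).
THETA_BOUNDS: tuple[float, float] = (-0.2, 0.2)


class ScalingDomainError(ValueError):
    """A value falls outside the domain of the log map."""


class ShiftScaler(BaseEstimator):
    """Invertible per-nucleus log min–max scaler.

    Parameters
    ----------
    a : float, default 10.0
        Logarithm base, shared across nuclei; must lie in [1.1, 10].
    theta_hn : float, default 0.0
        Additive offset applied after the log map, for the HN nucleus
        only (it is negligible for the heavy atoms and amide nitrogen).

    Attributes
    ----------
    ranges_ : dict
        ``nucleus -> (y_min, y_max)`` reference extrema in ppm, set by
        :meth:`fit`.
    """

    def __init__(self, a: float = 10.0, theta_hn: float = 0.0):
        self.a = a
        self.theta_hn = theta_hn

    def _validate(self) -> None:
        if not (A_BOUNDS[0] <= self.a <= A_BOUNDS[1]):
            raise ValueError(f"log base a={self.a} outside {A_BOUNDS}")

    def theta(self, nucleus: str) -> float:
        return self.theta_hn if nucleus == "HN" else 0.0

    def fit(self, reference: ShiftTable, y=None) -> "ShiftScaler":
        """Set per-nucleus reference ranges from an experimental table."""
        self._validate()
        ranges: dict[str, tuple[float, float]] = {}
        for nucleus in NUCLEI:
            _, vals = reference.nucleus_values(nucleus)
            if vals.size < 2:
                raise ValueError(
                    f"need at least two assigned {nucleus} shifts to fit a range")
            lo, hi = float(vals.min()), float(vals.max())
            if hi <= lo:
                raise ValueError(
                    f"degenerate {nucleus} reference range (all values {lo} ppm)")
            ranges[nucleus] = (lo, hi)
        self.ranges_ = ranges
        return self

    def transform(self, x, nucleus: str, residues=None) -> np.ndarray:
        """Map ppm values into the scaled projection space."""
        lo, hi = self.ranges_[nucleus]
        x = np.asarray(x, dtype=float)
        arg = (x - lo) / (hi - lo) + 1.0
        if np.any(arg <= 0):
            bad = np.atleast_1d(arg <= 0).nonzero()[0]
            where = (f"residue {np.atleast_1d(residues)[bad[0]]}"
                     if residues is not None else f"index {bad[0]}")
            raise ScalingDomainError(
                f"{nucleus} value {np.atleast_1d(x)[bad[0]]} ppm at {where} "
                f"falls below the scaling domain (y_min={lo}, y_max={hi})")
        return np.log(arg) / np.log(self.a) + self.theta(nucleus)

    def inverse_transform(self, s, nucleus: str) -> np.ndarray:
        """Map scaled values back to ppm (exact inverse of :meth:`transform`)."""
        lo, hi = self.ranges_[nucleus]
        s = np.asarray(s, dtype=float)
        return (np.power(self.a, s - self.theta(nucleus)) - 1.0) * (hi - lo) + lo

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "theta_hn": self.theta_hn,
            "ranges": {n: list(r) for n, r in self.ranges_.items()},
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ShiftScaler":
        scaler = cls(a=payload["a"], theta_hn=payload["theta_hn"])
        scaler.ranges_ = {n: tuple(r) for n, r in payload["ranges"].items()}
        return scaler


def fit_reference_range(reference: ShiftTable) -> ShiftScaler:
    """Fitted scaler with default hyperparameters (a=10, theta=0)."""
    return ShiftScaler().fit(reference)


def apply_scaling(x, scaler: ShiftScaler, nucleus: str) -> np.ndarray:
    return scaler.transform(x, nucleus)


def invert_scaling(s, scaler: ShiftScaler, nucleus: str) -> np.ndarray:
    return scaler.inverse_transform(s, nucleus)


def tune_hyperparameters(
    library: "ShiftLibrary",
    reference: ShiftTable,
    a_bounds: tuple[float, float] = A_BOUNDS,
    theta_bounds: tuple[float, float] = THETA_BOUNDS,
    n_starts: int = 4,
    tol: float = 1e-9,
) -> tuple[float, float]:
    """Tune (a, theta_HN) by minimising the constrained-regression residual.

    The objective evaluates, for each candidate (a, theta), the squared
    residual of the simplex-constrained fit in scaled space.  It can be
    multimodal, so a multi-start quasi-Newton (L-BFGS-B) loop is run from
    ``n_starts`` log-spaced bases.  When the objective is flat to within
    *tol* of the default point the defaults (a=10, theta=0) are kept.

    Returns
    -------
    (a, theta_hn) : tuple of float
    """
    from .regression import build_problem, solve_simplex_nnls

    def objective(params) -> float:
        a, theta = params
        scaler = ShiftScaler(a=float(a), theta_hn=float(theta)).fit(reference)
        problem = build_problem(library, reference, scaler)
        fit = solve_simplex_nnls(problem)
        return float(fit.residual_norm) ** 2

    default = (10.0, 0.0)
    default_obj = objective(default)

    starts = np.geomspace(a_bounds[0], a_bounds[1], n_starts)
    best_params, best_obj = default, default_obj
    for a0 in starts:
        res = minimize(
            objective, x0=[a0, 0.0], method="L-BFGS-B",
            bounds=[a_bounds, theta_bounds],
            options={"maxiter": 60, "eps": 1e-4},
        )
        if res.fun < best_obj:
            best_params, best_obj = (float(res.x[0]), float(res.x[1])), float(res.fun)
    # flat objective -> keep defaults
    if default_obj - best_obj <= tol * max(1.0, default_obj):
        return default
    return best_params
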