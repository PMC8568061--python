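"""Simplex-constrained ensemble-weight regression on chemical shifts.

The experimental shift vector ``y`` is modelled as a convex combination of
the library conformers' predicted shifts,

    y = w_1 X_1 + ... + w_n X_n + eps,   w_i >= 0,  sum w_i = 1,

so each coefficient is interpretable as the population of a conformational
state.  The solve is two-stage, mirroring the usual practice: a plain
non-negative least squares pass (KKT active set) followed by an
equality-constrained SLSQP refit on the simplex; an exact KKT polish on the
active set then sharpens the optimum.  Significant coefficients are kept by
a relative threshold ``w_j >= eps * max(w)`` and the model is refit on that
support before scoring.

Scoring uses the coefficient of determination per nucleus, computed in ppm
space (predictions mapped back through the inverse scaling), and the total
score is the product of the four per-nucleus R² values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize, nnls
from sklearn.base import BaseEstimator, RegressorMixin

from .io import NUCLEI, ShiftLibrary, ShiftTable, apply_exclusion_mask
from .scaling import ShiftScaler, tune_hyperparameters

logger = logging.getLogger(__name__)

#: Relative coefficient-selection threshold.
DEFAULT_EPS: float = 1e-5


@dataclass(frozen=True)
class RegressionProblem:
    """Assembled design for the constrained regression, in scaled space.

    Rows are (residue, nucleus) observations ordered by residue number and
    then by the canonical nucleus order; columns are library conformers.
    """

    design: np.ndarray                     # (n_obs, n_conformers)
    target: np.ndarray                     # (n_obs,)
    feature_index: tuple[tuple[int, str], ...]
    conformer_ids: tuple[str, ...]
    scaler: ShiftScaler

    def __post_init__(self) -> None:
        if self.design.shape != (len(self.feature_index), len(self.conformer_ids)):
            raise ValueError("design shape inconsistent with index labels")
        if self.target.shape != (len(self.feature_index),):
            raise ValueError("target length inconsistent with feature index")
        if not (np.isfinite(self.design).all() and np.isfinite(self.target).all()):
            raise ValueError("design/target contain non-finite entries; was the "
                             "exclusion mask applied?")

    def nucleus_rows(self, nucleus: str) -> np.ndarray:
        return np.array([i for i, (_, nuc) in enumerate(self.feature_index)
                         if nuc == nucleus], dtype=int)


@dataclass(frozen=True)
class EnsembleWeights:
    """Simplex weight vector over library conformers with its scores."""

    conformer_ids: tuple[str, ...]
    weights: np.ndarray
    support: tuple[int, ...]               # indices of selected conformers
    threshold_eps: float
    residual_norm: float
    per_atom_r2: Mapping[str, float] = field(default_factory=dict)
    total_r2: float | None = None

    def __post_init__(self) -> None:
        w = self.weights
        if np.any(w < -1e-10):
            raise ValueError("negative ensemble weight")
        if abs(w.sum() - 1.0) > 1e-8:
            raise ValueError(f"weights sum to {w.sum()}, not 1")

    def as_dict(self) -> dict[str, float]:
        return {cid: float(w) for cid, w in zip(self.conformer_ids, self.weights)}

    @property
    def support_ids(self) -> tuple[str, ...]:
        return tuple(self.conformer_ids[i] for i in self.support)


def build_problem(library: ShiftLibrary, reference: ShiftTable,
                  scaler: ShiftScaler) -> RegressionProblem:
    """Scale masked library/reference tables into a regression problem."""
    if len(library) == 0:
        raise ValueError("empty library")
    residues = library.residue_numbers
    if residues != reference.residue_numbers:
        raise ValueError("library and reference disagree on residues; apply "
                         "the exclusion mask first")
    feature_index = tuple((r, nuc) for r in residues for nuc in NUCLEI)
    for r, nuc in feature_index:
        if not reference.is_assigned(r, nuc):
            raise ValueError(f"reference missing ({r}, {nuc}); apply the "
                             "exclusion mask first")

    def column(table: ShiftTable) -> np.ndarray:
        out = np.empty(len(feature_index))
        for k, (r, nuc) in enumerate(feature_index):
            out[k] = table.values[(r, nuc)]
        return out

    raw_target = column(reference)
    raw_design = np.column_stack([column(t) for t in library.tables])
    target = np.empty_like(raw_target)
    design = np.empty_like(raw_design)
    for nucleus in NUCLEI:
        rows = [k for k, (_, nuc) in enumerate(feature_index) if nuc == nucleus]
        res = [feature_index[k][0] for k in rows]
        target[rows] = scaler.transform(raw_target[rows], nucleus, residues=res)
        design[rows, :] = scaler.transform(raw_design[rows, :], nucleus)
    return RegressionProblem(design=design, target=target,
                             feature_index=feature_index,
                             conformer_ids=library.conformer_ids, scaler=scaler)


# ---------------------------------------------------------------------------
# Solvers
# ---------------------------------------------------------------------------

def _kkt_polish(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                active_tol: float = 1e-10) -> np.ndarray:
    """Exact active-set polish of the simplex-constrained least squares.

    Solves the equality-constrained problem restricted to the passive set
    through its KKT system (minimum-norm solve, which also breaks ties
    among equal-residual solutions), dropping negative coordinates until
    feasible.  Returns the polished weights if they do not worsen the
    residual, else *w* unchanged.
    """
    n = X.shape[1]
    passive = np.flatnonzero(w > active_tol)
    if passive.size == 0:
        passive = np.array([int(np.argmax(w))])
    for _ in range(2 * n + 10):
        Xp = X[:, passive]
        k = passive.size
        kkt = np.zeros((k + 1, k + 1))
        kkt[:k, :k] = 2.0 * Xp.T @ Xp
        kkt[:k, k] = 1.0
        kkt[k, :k] = 1.0
        rhs = np.concatenate([2.0 * Xp.T @ y, [1.0]])
        sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
        wp = sol[:k]
        if wp.min() >= -1e-12:
            out = np.zeros(n)
            out[passive] = np.clip(wp, 0.0, None)
            out /= out.sum()
            if np.linalg.norm(y - X @ out) <= np.linalg.norm(y - X @ w) + 1e-12:
                return out
            return w
        passive = np.delete(passive, int(np.argmin(wp)))
        if passive.size == 0:
            return w
    return w


def _solve_simplex(X: np.ndarray, y: np.ndarray,
                   x0: np.ndarray | None = None) -> np.ndarray:
    """Minimise ||y - Xw||^2 over the probability simplex."""
    n = X.shape[1]
    if n == 1:
        return np.ones(1)
    if x0 is None:
        x0 = np.full(n, 1.0 / n)

    def fun(w):
        r = X @ w - y
        return float(r @ r)

    def jac(w):
        return 2.0 * X.T @ (X @ w - y)

    res = minimize(fun, x0=x0, jac=jac, method="SLSQP",
                   bounds=[(0.0, None)] * n,
                   constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                                 "jac": lambda w: np.ones(n)}],
                   options={"maxiter": 500, "ftol": 1e-14})
    w = np.clip(res.x, 0.0, None)
    s = w.sum()
    w = w / s if s > 0 else np.full(n, 1.0 / n)
    return _kkt_polish(X, y, w)


def solve_simplex_nnls(problem: RegressionProblem) -> EnsembleWeights:
    """Two-stage simplex-constrained NNLS solve (pre-selection weights)."""
    X, y = problem.design, problem.target
    n = X.shape[1]
    zero_cols = np.flatnonzero(np.linalg.norm(X, axis=0) == 0)
    if zero_cols.size:
        logger.warning("dropping %d all-zero design column(s): %s",
                       zero_cols.size,
                       [problem.conformer_ids[i] for i in zero_cols])
    keep = np.setdiff1d(np.arange(n), zero_cols)
    w0, _ = nnls(X[:, keep], y)
    s = w0.sum()
    x0 = w0 / s if s > 0 else np.full(keep.size, 1.0 / keep.size)
    w_kept = _solve_simplex(X[:, keep], y, x0=x0)
    w = np.zeros(n)
    w[keep] = w_kept
    return EnsembleWeights(
        conformer_ids=problem.conformer_ids, weights=w,
        support=tuple(range(n)), threshold_eps=DEFAULT_EPS,
        residual_norm=float(np.linalg.norm(y - X @ w)),
    )


def select_features(fit: EnsembleWeights, eps: float = DEFAULT_EPS) -> tuple[int, ...]:
    """Indices j with w_j >= eps * max(w) (inclusive comparison)."""
    w = fit.weights
    threshold = eps * w.max()
    return tuple(int(j) for j in np.flatnonzero(w >= threshold))


def refit_on_support(problem: RegressionProblem, support: Sequence[int],
                     eps: float = DEFAULT_EPS) -> EnsembleWeights:
    """Refit the simplex-constrained regression on the selected support.

    Conformers outside the support get weight exactly zero.
    """
    support = tuple(sorted(int(j) for j in support))
    if not support:
        raise ValueError("empty support")
    X, y = problem.design, problem.target
    sub = _solve_simplex(X[:, list(support)], y)
    w = np.zeros(X.shape[1])
    w[list(support)] = sub
    return EnsembleWeights(
        conformer_ids=problem.conformer_ids, weights=w, support=support,
        threshold_eps=eps,
        residual_norm=float(np.linalg.norm(y - X @ w)),
    )


# ---------------------------------------------------------------------------
# Scoring & prediction
# ---------------------------------------------------------------------------

def score(problem: RegressionProblem, fit: EnsembleWeights
          ) -> tuple[dict[str, float], float | None]:
    """Per-nucleus and total R², computed in ppm space.

    Predictions are mapped back to ppm through the inverse scaling so the
    per-nucleus scores are comparable to the shift-prediction literature.
    The total score is the product over the four nuclei; it is ``None``
    when any per-nucleus score is undefined (zero reference variance).
    """
    yhat_scaled = problem.design @ fit.weights
    per_atom: dict[str, float | None] = {}
    for nucleus in NUCLEI:
        rows = problem.nucleus_rows(nucleus)
        y_ppm = problem.scaler.inverse_transform(problem.target[rows], nucleus)
        yhat_ppm = problem.scaler.inverse_transform(yhat_scaled[rows], nucleus)
        tss = float(np.sum((y_ppm - y_ppm.mean()) ** 2))
        if tss == 0.0:
            logger.warning("zero reference variance for %s; R^2 undefined", nucleus)
            per_atom[nucleus] = None
            continue
        rss = float(np.sum((y_ppm - yhat_ppm) ** 2))
        per_atom[nucleus] = 1.0 - rss / tss
    total = combine_scores(per_atom)
    return per_atom, total


def combine_scores(per_atom: Mapping[str, float | None]) -> float | None:
    """Total score: product of per-nucleus R² over the backbone set."""
    values = [per_atom.get(nuc) for nuc in NUCLEI]
    if any(v is None for v in values):
        return None
    return float(np.prod([float(v) for v in values]))


def predict_reference(fit: EnsembleWeights, library: ShiftLibrary) -> ShiftTable:
    """Weighted convex combination of library shifts in ppm space."""
    residues = library.tables[0].residues
    values: dict[tuple[int, str], float] = {}
    for r, _ in residues:
        for nuc in NUCLEI:
            if all(t.is_assigned(r, nuc) for t in library.tables):
                values[(r, nuc)] = float(sum(
                    w * t.values[(r, nuc)]
                    for w, t in zip(fit.weights, library.tables)))
    return ShiftTable(entity_id="regression", residues=residues, values=values)


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class EnsembleSelector(RegressorMixin, BaseEstimator):
    """Simplex-constrained ensemble-weight regressor.

    scikit-learn style estimator: ``fit(X, y)`` takes a design matrix with
    one row per observation (a residue/nucleus pair, already scaled) and
    one column per candidate conformer, and estimates a sparse non-negative
    weight vector summing to one.  :meth:`fit_tables` runs the full
    domain workflow from shift tables (exclusion mask, scaling and
    optional hyperparameter tuning, solve, feature selection, refit,
    ppm-space scoring).

    Parameters
    ----------
    eps : float, default 1e-5
        Relative coefficient-selection threshold ``w_j >= eps * max(w)``.
    a : float, default 10.0
        Logarithm base of the scaling map (``fit_tables`` only).
    theta_hn : float, default 0.0
        Amide-proton scaling offset (``fit_tables`` only).
    tune : bool, default False
        Tune (a, theta_hn) by nested optimisation before the final solve.

    Attributes
    ----------
    weights_ : ndarray of shape (n_conformers,)
        Final simplex weights (zeros off-support).
    support_ : tuple of int
        Indices of the selected conformers.
    residual_norm_ : float
        Scaled-space residual norm of the final fit.
    per_atom_r2_, total_r2_ :
        ppm-space scores (``fit_tables`` only).
    """

    def __init__(self, eps: float = DEFAULT_EPS, a: float = 10.0,
                 theta_hn: float = 0.0, tune: bool = False):
        self.eps = eps
        self.a = a
        self.theta_hn = theta_hn
        self.tune = tune

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per element of y")
        ids = tuple(str(i) for i in range(X.shape[1]))
        problem = RegressionProblem(
            design=X, target=y,
            feature_index=tuple((k, "CA") for k in range(X.shape[0])),
            conformer_ids=ids, scaler=ShiftScaler())
        pre = solve_simplex_nnls(problem)
        support = select_features(pre, eps=self.eps)
        final = refit_on_support(problem, support, eps=self.eps)
        self.n_features_in_ = X.shape[1]
        self.weights_ = final.weights
        self.coef_ = final.weights
        self.support_ = final.support
        self.residual_norm_ = final.residual_norm
        self.result_ = final
        return self

    def fit_tables(self, library: ShiftLibrary, reference: ShiftTable
                   ) -> "EnsembleSelector":
        """Full workflow from (library, reference) shift tables."""
        library, reference, excluded = apply_exclusion_mask(library, reference)
        a, theta = self.a, self.theta_hn
        if self.tune:
            a, theta = tune_hyperparameters(library, reference)
        scaler = ShiftScaler(a=a, theta_hn=theta).fit(reference)
        problem = build_problem(library, reference, scaler)
        pre = solve_simplex_nnls(problem)
        support = select_features(pre, eps=self.eps)
        final = refit_on_support(problem, support, eps=self.eps)
        per_atom, total = score(problem, final)
        self.n_features_in_ = len(library)
        self.weights_ = final.weights
        self.coef_ = final.weights
        self.support_ = final.support
        self.residual_norm_ = final.residual_norm
        self.excluded_residues_ = excluded
        self.scaler_ = scaler
        self.a_ = a
        self.theta_hn_ = theta
        self.problem_ = problem
        self.per_atom_r2_ = per_atom
        self.total_r2_ = total
        self.result_ = EnsembleWeights(
            conformer_ids=final.conformer_ids, weights=final.weights,
            support=final.support, threshold_eps=self.eps,
            residual_norm=final.residual_norm, per_atom_r2=per_atom,
            total_r2=total)
        self.library_ = library
        self.reference_ = reference
        return self

    def predict(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights_

    def predict_table(self) -> ShiftTable:
        """Regression-predicted shift table (``fit_tables`` only)."""
        return predict_reference(self.result_, self.library_)
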