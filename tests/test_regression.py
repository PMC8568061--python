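"""Constrained regression: solve, selection, refit, scoring, prediction."""

import itertools

import numpy as np
import pytest

from shiftensemble.io import NUCLEI, ShiftLibrary, ShiftTable
from shiftensemble.regression import (EnsembleSelector, build_problem,
                                      combine_scores, predict_reference,
                                      refit_on_support, score,
                                      select_features, solve_simplex_nnls)
from shiftensemble.scaling import ShiftScaler

from conftest import array_problem, random_library, random_table


def simplex_grid_minimum(X, y, step=0.001, coarse=0.02):
    """Brute-force minimiser of ||y - Xw||^2 over a step-resolution simplex
    grid.

    The objective is convex, so a full coarse grid followed by a full
    fine grid restricted to the coarse optimum's neighbourhood finds the
    global fine-grid optimum.
    """
    n = X.shape[1]

    def search(lo, hi, s):
        best_w, best_val = None, np.inf
        axes = [np.arange(max(lo[i], 0.0), min(hi[i], 1.0) + s / 2, s)
                for i in range(n - 1)]
        for combo in itertools.product(*axes):
            last = 1.0 - sum(combo)
            if last < -1e-12:
                continue
            w = np.array(list(combo) + [max(last, 0.0)])
            r = X @ w - y
            val = r @ r
            if val < best_val:
                best_w, best_val = w, val
        return best_w, best_val

    w_coarse, _ = search(np.zeros(n), np.ones(n), coarse)
    lo = w_coarse[:-1] - coarse
    hi = w_coarse[:-1] + coarse
    w_fine, val = search(lo, hi, step)
    return w_fine, val


def test_build_problem_shapes_and_elementwise_scaling(rng):
    library = random_library(rng, n_conformers=3, n_res=5)
    reference = random_table(rng, n_res=5)
    scaler = ShiftScaler(a=4.0).fit(reference)
    problem = build_problem(library, reference, scaler)
    assert problem.design.shape == (20, 3)
    for k, (r, nuc) in enumerate(problem.feature_index):
        for j, table in enumerate(library.tables):
            expected = scaler.transform(table.values[(r, nuc)], nuc)
            assert problem.design[k, j] == pytest.approx(float(expected))
        assert problem.target[k] == pytest.approx(
            float(scaler.transform(reference.values[(r, nuc)], nuc)))


def test_build_problem_requires_masked_inputs(rng):
    library = random_library(rng, n_conformers=2, n_res=4)
    reference = random_table(rng, n_res=4, drop={(2, "CB")})
    scaler = ShiftScaler().fit(reference)
    with pytest.raises(ValueError, match="exclusion"):
        build_problem(library, reference, scaler)


def test_single_column_equal_to_target_gets_weight_one(rng):
    y = rng.normal(size=15)
    problem = array_problem(y[:, None], y)
    fit = solve_simplex_nnls(problem)
    assert fit.weights == pytest.approx([1.0])
    assert fit.residual_norm < 1e-12


def test_known_mixture_recovered_exactly(rng):
    X = rng.normal(size=(40, 3))
    w_true = np.array([0.5, 0.3, 0.2])
    fit = solve_simplex_nnls(array_problem(X, X @ w_true))
    np.testing.assert_allclose(fit.weights, w_true, atol=1e-6)


@pytest.mark.parametrize("n_col", [3, 4])
def test_solution_matches_simplex_grid_oracle(rng, n_col):
    X = rng.normal(size=(12, n_col))
    y = rng.normal(size=12)
    fit = solve_simplex_nnls(array_problem(X, y))
    w_grid, val_grid = simplex_grid_minimum(X, y)
    assert np.max(np.abs(fit.weights - w_grid)) <= 1.5e-3
    assert fit.residual_norm ** 2 <= val_grid + 1e-9


def test_zero_column_dropped_with_warning(rng, caplog):
    X = rng.normal(size=(10, 3))
    X[:, 1] = 0.0
    w_true = np.array([0.6, 0.0, 0.4])
    with caplog.at_level("WARNING"):
        fit = solve_simplex_nnls(array_problem(X, X @ w_true))
    assert "all-zero" in caplog.text
    np.testing.assert_allclose(fit.weights, w_true, atol=1e-8)


def test_selection_threshold_is_relative_and_inclusive(rng):
    problem = array_problem(rng.normal(size=(6, 2)), rng.normal(size=6))
    fit = solve_simplex_nnls(problem)
    # near-point-mass: tiny coefficient falls below 1e-5 * max
    fit2 = fit.__class__(conformer_ids=("a", "b"),
                         weights=np.array([1.0 - 1e-12, 1e-12]),
                         support=(0, 1), threshold_eps=1e-5,
                         residual_norm=0.0)
    assert select_features(fit2) == (0,)
    fit3 = fit.__class__(conformer_ids=("a", "b", "c"),
                         weights=np.full(3, 1 / 3), support=(0, 1, 2),
                         threshold_eps=1e-5, residual_norm=0.0)
    assert select_features(fit3) == (0, 1, 2)


def test_selection_matches_direct_scan(rng):
    from shiftensemble.regression import EnsembleWeights
    for _ in range(200):
        w = rng.dirichlet(np.full(8, 0.3))
        fit = EnsembleWeights(conformer_ids=tuple("abcdefgh"), weights=w,
                              support=tuple(range(8)), threshold_eps=1e-5,
                              residual_norm=0.0)
        expected = tuple(j for j in range(8) if w[j] >= 1e-5 * w.max())
        assert select_features(fit) == expected


def test_refit_single_support_is_point_mass(rng):
    problem = array_problem(rng.normal(size=(10, 4)), rng.normal(size=10))
    fit = refit_on_support(problem, [2])
    assert fit.weights[2] == 1.0
    assert fit.weights.sum() == 1.0
    assert np.count_nonzero(fit.weights) == 1


def test_refit_on_full_support_does_not_worsen(rng):
    for seed in range(5):
        gen = np.random.default_rng(seed)
        problem = array_problem(gen.normal(size=(20, 6)), gen.normal(size=20))
        pre = solve_simplex_nnls(problem)
        post = refit_on_support(problem, range(6))
        assert post.residual_norm <= pre.residual_norm + 1e-9


def test_selection_then_refit_recovers_mixture(rng):
    X = rng.normal(size=(60, 25))
    w_true = np.zeros(25)
    w_true[[3, 11, 19]] = (0.5, 0.3, 0.2)
    problem = array_problem(X, X @ w_true)
    pre = solve_simplex_nnls(problem)
    support = select_features(pre)
    final = refit_on_support(problem, support)
    np.testing.assert_allclose(final.weights, w_true, atol=1e-6)
    off_support = np.setdiff1d(np.arange(25), final.support)
    assert np.all(final.weights[off_support] == 0.0)


def test_simplex_invariants_on_random_problems(rng):
    for seed in range(20):
        gen = np.random.default_rng(seed)
        problem = array_problem(gen.normal(size=(15, 7)), gen.normal(size=15))
        fit = refit_on_support(problem, select_features(solve_simplex_nnls(problem)))
        assert np.all(fit.weights >= 0)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-8)


def test_active_set_recall_under_noise(rng):
    """Selection keeps the truly active conformers under 1%-of-range noise."""
    hits = total = 0
    for seed in range(20):
        gen = np.random.default_rng(seed)
        X = gen.normal(size=(40, 20))
        w_true = np.zeros(20)
        w_true[gen.choice(20, 3, replace=False)] = (0.5, 0.3, 0.2)
        span = X.max() - X.min()
        y = X @ w_true + gen.normal(0, 0.01 * span, 40)
        problem = array_problem(X, y)
        support = set(select_features(solve_simplex_nnls(problem)))
        active = set(np.flatnonzero(w_true))
        hits += len(active & support)
        total += len(active)
    assert hits / total >= 0.9


def test_perfect_prediction_scores_one(rng):
    library = random_library(rng, n_conformers=3, n_res=6)
    reference = library.tables[2]
    scaler = ShiftScaler().fit(reference)
    problem = build_problem(library, reference, scaler)
    fit = refit_on_support(problem, [2])
    per_atom, total = score(problem, fit)
    for nucleus in NUCLEI:
        assert per_atom[nucleus] == pytest.approx(1.0, abs=1e-10)
    assert total == pytest.approx(1.0, abs=1e-9)


def test_constant_prediction_scores_zero(rng):
    reference = random_table(rng, n_res=6)
    # single conformer whose shifts equal the per-nucleus reference mean
    mean_values = {}
    for nuc in NUCLEI:
        _, vals = reference.nucleus_values(nuc)
        for r in reference.residue_numbers:
            mean_values[(r, nuc)] = float(vals.mean())
    flat = ShiftTable("flat", reference.residues, mean_values)
    library = ShiftLibrary(conformer_ids=("flat",), tables=(flat,))
    scaler = ShiftScaler().fit(reference)
    problem = build_problem(library, reference, scaler)
    fit = refit_on_support(problem, [0])
    per_atom, _ = score(problem, fit)
    for nucleus in NUCLEI:
        assert per_atom[nucleus] == pytest.approx(0.0, abs=1e-9)


def test_total_score_is_product_of_atom_scores():
    per_atom = {"HN": 0.8737, "NH": 0.9146, "CA": 0.9686, "CB": 0.9963}
    assert combine_scores(per_atom) == pytest.approx(0.7711, abs=5e-4)
    assert combine_scores({**per_atom, "CB": None}) is None


def test_predicted_table_is_convex_combination(rng):
    library = random_library(rng, n_conformers=4, n_res=5)
    problem_w = rng.dirichlet(np.ones(4))
    from shiftensemble.regression import EnsembleWeights
    fit = EnsembleWeights(conformer_ids=library.conformer_ids,
                          weights=problem_w, support=(0, 1, 2, 3),
                          threshold_eps=1e-5, residual_norm=0.0)
    predicted = predict_reference(fit, library)
    for key in library.tables[0].values:
        expected = sum(w * t.values[key]
                       for w, t in zip(problem_w, library.tables))
        assert predicted.values[key] == pytest.approx(expected, abs=1e-12)
    # point mass reproduces a member; equal weights give the mean
    point = EnsembleWeights(conformer_ids=library.conformer_ids,
                            weights=np.eye(4)[1], support=(1,),
                            threshold_eps=1e-5, residual_norm=0.0)
    assert predict_reference(point, library).values == library.tables[1].values


def test_estimator_follows_sklearn_conventions(rng):
    X = rng.normal(size=(30, 6))
    w_true = np.zeros(6)
    w_true[[0, 4]] = (0.7, 0.3)
    y = X @ w_true
    est = EnsembleSelector(eps=1e-5)
    assert est.get_params()["eps"] == 1e-5
    est.set_params(eps=1e-4).fit(X, y)
    np.testing.assert_allclose(est.weights_, w_true, atol=1e-6)
    np.testing.assert_allclose(est.predict(X), y, atol=1e-6)
    assert est.score(X, y) == pytest.approx(1.0)
    assert est.n_features_in_ == 6
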