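"""The five imputation methods and cross-validated k selection."""

import numpy as np
import pytest

import markerimpute as mi
from markerimpute.imputers import (
    EMImputer,
    KNNMarkerImputer,
    MeanImputer,
    RandomForestImputer,
    SVDImputer,
)

from conftest import toy_matrix

NA = np.nan


# ---------------------------------------------------------------------------
# shared contracts

METHODS = {
    "MNI": lambda gm: mi.impute_mni(gm),
    "kNNI": lambda gm: mi.impute_knni(gm, k=3),
    "SVDI": lambda gm: mi.impute_svdi(gm, k=2),
    "EMI": lambda gm: mi.impute_emi(gm),
    "RFI": lambda gm: mi.impute_rfi(gm, n_trees=20, seed=4),
}


@pytest.mark.parametrize("method", list(METHODS))
def test_observed_cells_unchanged_and_output_complete(method, small_masked):
    gm = small_masked.observed
    res = METHODS[method](gm)
    out = res.completed.values
    assert not np.isnan(out).any()
    obs = ~gm.missing_mask
    np.testing.assert_array_equal(out[obs], gm.values[obs])
    assert len(res.convergence_trace) == res.iterations_run or method in ("MNI", "kNNI")


@pytest.mark.parametrize("method", ["MNI", "kNNI", "SVDI", "EMI"])
def test_deterministic_methods_are_reproducible(method, small_masked):
    a = METHODS[method](small_masked.observed).completed.values
    b = METHODS[method](small_masked.observed).completed.values
    np.testing.assert_array_equal(a, b)


def test_rfi_is_seed_deterministic(small_masked):
    gm = small_masked.observed.select_markers(range(15))
    a = mi.impute_rfi(gm, n_trees=10, seed=9).completed.values
    b = mi.impute_rfi(gm, n_trees=10, seed=9).completed.values
    np.testing.assert_array_equal(a, b)


def test_all_missing_marker_is_an_error():
    gm = toy_matrix([[1, NA], [-1, NA]])
    for fn in METHODS.values():
        with pytest.raises(ValueError):
            fn(gm)


# ---------------------------------------------------------------------------
# MNI


def test_mni_fills_column_means():
    gm = toy_matrix([[1, 0], [1, 1], [-1, NA], [NA, NA]],
                    coding=mi.Coding.MINUS1_0_1)
    out = mi.impute_mni(gm).completed.values
    assert out[3, 0] == pytest.approx(1 / 3)
    assert out[2, 1] == pytest.approx(0.5)
    assert out[3, 1] == pytest.approx(0.5)


def test_mni_on_complete_matrix_is_identity(small_population):
    gm = small_population.genotypes
    out = mi.impute_mni(gm).completed.values
    np.testing.assert_array_equal(out, gm.values)


# ---------------------------------------------------------------------------
# kNNI


def test_knni_twin_marker_supplies_the_fill():
    # marker 0 == marker 1 except one hole; nearest neighbour at d=0
    vals = np.array([
        [NA, 1.0, -1.0],
        [1, 1, 1],
        [-1, -1, -1],
        [1, 1, -1],
        [-1, -1, 1],
    ])
    out = KNNMarkerImputer(k=1).fit_transform(vals)
    assert out[0, 0] == 1.0


def test_knni_weighted_average_matches_hand_computation():
    # target marker A observed [-1,1,-1,1] with a hole at row 0 (prefill 0);
    # neighbour B at d=1 carries value 1, neighbour C at d=sqrt(5) carries -1;
    # fill = (1*1 + (1/5)*(-1)) / (1 + 1/5) = 2/3
    A = [NA, -1, 1, -1, 1]
    B = [1, -1, 1, -1, 1]
    C = [-1, 1, 1, -1, 1]
    vals = np.array([A, B, C], dtype=float).T
    out = KNNMarkerImputer(k=2).fit_transform(vals)
    assert out[0, 0] == pytest.approx(2 / 3)

    # with k=1 only the d=1 neighbour contributes
    out1 = KNNMarkerImputer(k=1).fit_transform(vals)
    assert out1[0, 0] == pytest.approx(1.0)


def test_knni_negative_ld_neighbour_found_via_flip():
    # marker 1 is the exact sign-flip of marker 0: the flipped copy sits at
    # distance 0 and its (flipped) values fill the hole exactly
    vals = np.array([
        [NA, -1.0, 1.0],
        [1, -1, 1],
        [-1, 1, -1],
        [1, -1, -1],
        [-1, 1, 1],
    ])
    out = KNNMarkerImputer(k=1).fit_transform(vals)
    assert out[0, 0] == 1.0  # flip of -1 at the twin's row 0


def test_knni_k_bounds():
    vals = np.array([[NA, 1.0], [1, 1], [-1, -1]])
    with pytest.raises(ValueError, match="k must be"):
        KNNMarkerImputer(k=3).fit_transform(vals)  # 2(n-1) = 2


# ---------------------------------------------------------------------------
# SVDI


def test_svdi_recovers_rank_one_holes_to_machine_precision():
    rng = np.random.default_rng(0)
    u = rng.standard_normal(12)
    v = rng.standard_normal(8)
    full = np.outer(u, v)
    holes = rng.random(full.shape) < 0.15
    X = full.copy()
    X[holes] = np.nan
    out = SVDImputer(k=1, max_iter=50, tol=1e-12).fit_transform(X)
    np.testing.assert_allclose(out, full, atol=1e-8)


def test_svdi_complete_matrix_is_identity(small_population):
    gm = small_population.genotypes
    est = SVDImputer(k=3)
    out = est.fit_transform(gm.values)
    np.testing.assert_array_equal(out, gm.values)
    assert est.iterations_run_ == 1


def test_svdi_matches_independent_reimplementation():
    rng = np.random.default_rng(7)
    base = rng.standard_normal((6, 2)) @ rng.standard_normal((2, 6))
    noise = 0.1 * rng.standard_normal((6, 6))
    full = base + noise
    holes = rng.random((6, 6)) < 0.2
    holes[:, holes.all(axis=0)] = False
    X = full.copy()
    X[holes] = np.nan
    k, max_iter, tol = 2, 10, 0.02

    # straight-line reference: prefill, then iterate svd + per-column lstsq
    M = X.copy()
    mu = np.nanmean(X, axis=0)
    for j in range(6):
        M[np.isnan(X[:, j]), j] = mu[j]
    prev_rss = None
    for _ in range(max_iter):
        U = np.linalg.svd(M, full_matrices=False)[0][:, :k]
        rss = 0.0
        for j in range(6):
            o = ~np.isnan(X[:, j])
            b = np.linalg.lstsq(U[o], X[o, j], rcond=None)[0]
            pred = U @ b
            rss += float(((X[o, j] - pred[o]) ** 2).sum())
            M[~o, j] = pred[~o]
        if prev_rss is not None and abs(prev_rss - rss) / rss < tol:
            break
        prev_rss = rss

    out = SVDImputer(k=k, max_iter=max_iter, tol=tol).fit_transform(X)
    np.testing.assert_allclose(out, np.where(np.isnan(X), M, X), atol=1e-8)


# ---------------------------------------------------------------------------
# EMI


def test_emi_complete_matrix_is_identity(small_population):
    gm = small_population.genotypes
    est = EMImputer()
    out = est.fit_transform(gm.values)
    np.testing.assert_array_equal(out, gm.values)


def test_emi_duplicate_individual_supplies_the_fill():
    rng = np.random.default_rng(3)
    X = rng.choice([-1.0, 1.0], size=(6, 30))
    X[5] = X[4]  # duplicated individual
    X[5, 0] = np.nan
    out = EMImputer(tol=1e-9, max_iter=500, ridge=1e-10).fit_transform(X)
    assert out[5, 0] == pytest.approx(X[4, 0], abs=1e-6)


def test_emi_fills_equal_conditional_mvn_oracle():
    rng = np.random.default_rng(11)
    L = rng.standard_normal((8, 8)) * 0.4 + np.eye(8)
    X = (L @ rng.standard_normal((8, 12)))
    holes = rng.random((8, 12)) < 0.15
    holes[:, holes.all(axis=0)] = False
    Xm = X.copy()
    Xm[holes] = np.nan
    est = EMImputer(tol=1e-10, max_iter=1000)
    out = est.fit_transform(Xm)
    mu, S = est.mu_, est.sigma_
    # independent Schur-complement conditional expectation at the fixed point
    for j in range(12):
        mis = np.isnan(Xm[:, j])
        if not mis.any():
            continue
        o = ~mis
        cond = mu[mis] + S[np.ix_(mis, o)] @ np.linalg.inv(S[np.ix_(o, o)]) @ (
            Xm[o, j] - mu[o]
        )
        np.testing.assert_allclose(out[mis, j], cond, atol=1e-4)


# ---------------------------------------------------------------------------
# RFI


def test_rfi_twin_marker_supplies_the_fills():
    rng = np.random.default_rng(13)
    X = rng.choice([-1.0, 1.0], size=(30, 8))
    X[:, 1] = X[:, 0]
    holes = rng.choice(30, size=5, replace=False)
    X[holes, 0] = np.nan
    out = RandomForestImputer(n_trees=30, random_state=0).fit_transform(X)
    np.testing.assert_allclose(out[holes, 0], X[holes, 1], atol=1e-9)


def test_rfi_constant_marker_filled_with_the_constant():
    rng = np.random.default_rng(14)
    X = rng.choice([-1.0, 1.0], size=(20, 5))
    X[:, 2] = 1.0
    X[3:6, 2] = np.nan
    out = RandomForestImputer(n_trees=10, random_state=0).fit_transform(X)
    np.testing.assert_allclose(out[3:6, 2], 1.0)


def test_rfi_agrees_with_independent_reference_sweep():
    # independent straight-line missForest-style loop, same hyperparameters
    from sklearn.ensemble import RandomForestRegressor

    rng = np.random.default_rng(17)
    pop = mi.simulate_population(
        n_founders=6, n_families=3, lines_per_family=10, n_markers=40,
        n_chromosomes=2, seed=18,
    )
    X = pop.genotypes.values.copy()
    holes = rng.random(X.shape) < 0.3
    holes[:, holes.all(axis=0)] = False
    Xm = X.copy()
    Xm[holes] = np.nan

    est = RandomForestImputer(n_trees=50, random_state=1)
    out = est.fit_transform(Xm)

    obs = ~np.isnan(Xm)
    M = Xm.copy()
    mu = np.nanmean(Xm, axis=0)
    for j in range(M.shape[1]):
        M[~obs[:, j], j] = mu[j]
    order = np.argsort((~obs).mean(axis=0), kind="stable")
    prev = M.copy()
    deltas = []
    final = None
    for sweep in range(10):
        for j in order:
            if obs[:, j].all():
                continue
            o = obs[:, j]
            others = np.delete(M, j, axis=1)
            rf = RandomForestRegressor(
                n_estimators=50, max_features=1.0, min_samples_leaf=5,
                bootstrap=True, random_state=1000 + sweep * 100 + int(j), n_jobs=1,
            )
            rf.fit(others[o], Xm[o, j])
            M[~o, j] = rf.predict(others[~o])
        cols = np.flatnonzero((~obs).any(axis=0))
        dn = ((M - prev)[:, cols] ** 2).sum() / (M[:, cols] ** 2).sum()
        deltas.append(dn)
        if len(deltas) >= 2 and deltas[-1] > deltas[-2]:
            final = prev
            break
        prev = M.copy()
    if final is None:
        final = M

    r = np.corrcoef(out[holes], final[holes])[0, 1]
    assert r > 0.95  # tree randomness precludes exact equality


# ---------------------------------------------------------------------------
# k selection


def test_select_k_prefers_rank_one_for_low_rank_matrix():
    rng = np.random.default_rng(23)
    full = np.outer(rng.standard_normal(20), rng.standard_normal(15))
    holes = rng.random(full.shape) < 0.1
    holes[:, holes.all(axis=0)] = False
    X = full.copy()
    X[holes] = np.nan
    gm = toy_matrix(X, continuous=True)
    rep = mi.select_k_cv(gm, "svdi", [1, 5], n_folds=4, seed=2)
    assert rep.chosen_k == 1

    single = mi.select_k_cv(gm, "svdi", [3], n_folds=3, seed=2)
    assert single.chosen_k == 3 and single.cv_error_per_k.shape == (1,)


def test_select_k_rejects_invalid_grid(small_masked):
    with pytest.raises(ValueError, match="invalid k"):
        mi.select_k_cv(small_masked.observed, "svdi", [1, 10_000], seed=0)
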