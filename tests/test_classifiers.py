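"""PLS-DA against a least-squares oracle, VIP identities, membership
rescaling, and random-forest OOB screening."""

import numpy as np
import pytest

from chemfuse import (PLSDA, RandomForest, mtry_candidates, pick_mtry,
                      rescale_rows, rf_screen)


def separable_data(m=28, p=5, gap=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(m, p))
    y = np.repeat(["A", "B"], m // 2)
    X[:, 0] += np.where(y == "A", 0.0, gap)
    return X, list(y)


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

def test_separable_two_class_problem_is_perfect_with_one_lv():
    X, y = separable_data(gap=10.0)
    res = PLSDA(X, y).fit(max_lv=1)
    assert res.n_latent == 1
    assert np.array_equal(res.predict(X).hard_classes(), y)


def test_full_rank_predictions_match_least_squares_oracle():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(8, 3))
    y = ["A", "B", "A", "B", "B", "A", "B", "A"]
    res = PLSDA(X, y).fit(max_lv=3, n_latent=3)
    pred = res.decision_values(X)
    # oracle: ordinary least squares of centred one-hot Y on autoscaled X
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    Y = np.stack([(np.array(y) == c).astype(float) for c in ("A", "B")], 1)
    Yc = Y - Y.mean(0)
    beta, *_ = np.linalg.lstsq(Xs, Yc, rcond=None)
    np.testing.assert_allclose(pred, Xs @ beta + Y.mean(0), atol=1e-8)


def test_cv_q2_has_one_entry_per_candidate_lv():
    X, y = separable_data(m=30, p=6)
    res = PLSDA(X, y).fit(max_lv=4)
    assert res.cv_q2.shape == (4,)


def test_membership_rescaling_affine_map():
    out = rescale_rows(np.array([[0.9, 0.3, -0.1]]))
    np.testing.assert_allclose(out, [[1.0, 0.4, 0.0]])
    flat = rescale_rows(np.array([[0.5, 0.5, 0.5]]))
    np.testing.assert_allclose(flat, [[0.5, 0.5, 0.5]])


def test_single_class_rejected_at_construction():
    with pytest.raises(ValueError, match="2 classes"):
        PLSDA(np.zeros((6, 3)), ["A"] * 6)


def test_zero_variance_columns_dropped_with_warning_and_ignored():
    X, y = separable_data()
    Xz = np.hstack([X, np.full((X.shape[0], 1), 7.0)])
    with pytest.warns(UserWarning, match="zero-variance"):
        res = PLSDA(Xz, y).fit(max_lv=2)
    base = PLSDA(X, y).fit(max_lv=2)
    np.testing.assert_allclose(res.decision_values(Xz),
                               base.decision_values(X), atol=1e-10)


# ---------------------------------------------------------------------------
# VIP
# ---------------------------------------------------------------------------

def test_vip_is_exactly_one_for_a_single_variable():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(20, 1)) + np.repeat([0.0, 2.0], 10)[:, None]
    y = np.repeat(["A", "B"], 10)
    res = PLSDA(X, y).fit(max_lv=1)
    np.testing.assert_allclose(res.vip(), [1.0], atol=1e-12)


def test_mean_squared_vip_is_one_on_any_fitted_model():
    for seed in range(3):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(24, 11))
        y = list(rng.choice(["A", "B", "C"], 24))
        if len(set(y)) < 2:
            continue
        res = PLSDA(X, y).fit(max_lv=4)
        v = res.vip()
        assert np.mean(v ** 2) == pytest.approx(1.0, rel=1e-10)


def test_informative_variable_has_maximal_vip_above_one():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(40, 21))
    y = np.repeat(["A", "B"], 20)
    X[:, 4] += np.where(y == "A", 0.0, 3.0)
    res = PLSDA(X, list(y)).fit(max_lv=2)
    v = res.vip()
    assert np.argmax(v) == 4
    assert v[4] > 1.0


# ---------------------------------------------------------------------------
# random forest
# ---------------------------------------------------------------------------

def test_mtry_defaults_match_floor_square_root():
    assert mtry_candidates(2387) == (48, 38, 58)
    assert mtry_candidates(1097) == (33, 23, 43)
    assert mtry_candidates(4) == (2, 1, 4)  # range clipped to [1, p]


def test_mtry_ties_resolve_toward_the_default():
    errors = {40: 0.10, 43: 0.10, 50: 0.25}
    assert pick_mtry(errors, default=45) == 43  # distance 2 beats distance 5
    assert pick_mtry({40: 0.1, 50: 0.1}, default=45) == 40  # equidistant


def test_rf_memberships_are_vote_fractions_summing_to_one():
    X, y = separable_data(m=24)
    res = RandomForest(X, y).fit(ntree_init=100, seed=0)
    memb = res.predict(X)
    np.testing.assert_allclose(memb.values.sum(axis=1), 1.0, atol=1e-12)
    assert np.array_equal(memb.hard_classes(), y)


def test_rf_screen_is_reproducible_under_fixed_seed():
    X, y = separable_data(m=26, p=8, gap=1.0, seed=4)
    a = rf_screen(X, y, ntree_init=80, seed=5)
    b = rf_screen(X, y, ntree_init=80, seed=5)
    assert (a.n_tree, a.mtry) == (b.n_tree, b.mtry)
    np.testing.assert_array_equal(a.oob_error_by_ntree, b.oob_error_by_ntree)
    assert a.oob_error_by_mtry == b.oob_error_by_mtry


def test_rf_screen_n_tree_is_minimal_for_the_overall_minimum():
    X, y = separable_data(m=26, p=8, gap=1.5, seed=6)
    cfg = rf_screen(X, y, ntree_init=120, seed=7)
    errs = cfg.oob_error_by_ntree
    assert errs[cfg.n_tree - 1] == errs.min()
    assert 1 <= cfg.n_tree <= 120


def test_pure_noise_forest_has_chance_level_oob_error():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(200 + seed)
        X = rng.normal(size=(30, 10))
        y = np.repeat(["A", "B"], 15)
        res = RandomForest(X, list(y)).fit(ntree_init=100, seed=seed)
        if 0.3 <= res.oob_error <= 0.7:
            hits += 1
    assert hits >= 18


def test_single_overwhelming_predictor_drives_oob_error_down():
    X, y = separable_data(m=30, p=10, gap=6.0, seed=8)
    res = RandomForest(X, y).fit(ntree_init=150, seed=9)
    assert res.oob_error < 0.1
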