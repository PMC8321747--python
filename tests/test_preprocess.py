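"""Pretreatment chain: COW optimality, grid bookkeeping, derivative
behaviour, and band deletion."""

import numpy as np
import pytest

from chemfuse import (cow_align, cow_brute_force, downsample_every_k,
                      default_design, generate_block, pretreat_ftir,
                      pretreat_lc, remove_bands, sg_second_derivative)
from helpers import make_block


def gaussian(x, center, width=0.3):
    return np.exp(-0.5 * ((x - center) / width) ** 2)


# ---------------------------------------------------------------------------
# correlation-optimized warping
# ---------------------------------------------------------------------------

def test_cow_self_alignment_yields_identity_map_and_unit_correlations():
    x = np.linspace(0, 10, 200)
    ref = gaussian(x, 3) + 0.7 * gaussian(x, 7, 0.5)
    block = make_block(ref[None, :], x)
    res = cow_align(block, ref, segment_length=50, slack=10)
    assert all(t == s for t, s in res.node_maps[0])
    n_segments = len(res.node_maps[0]) - 1
    assert res.scores[0] == pytest.approx(n_segments, abs=1e-9)
    np.testing.assert_allclose(res.aligned[0], ref, atol=1e-12)


def test_cow_recovers_five_point_shift():
    x = np.linspace(0, 10, 200)
    dt = x[1] - x[0]
    ref = gaussian(x, 3) + 0.7 * gaussian(x, 7, 0.5)
    shifted = gaussian(x, 3 + 5 * dt) + 0.7 * gaussian(x, 7 + 5 * dt, 0.5)
    block = make_block(shifted[None, :], x)
    res = cow_align(block, ref, segment_length=50, slack=8)
    corr = np.corrcoef(res.aligned[0], ref)[0, 1]
    assert corr >= 0.99


@pytest.mark.parametrize("trial", range(6))
@pytest.mark.parametrize("slack", [1, 2])
def test_cow_dp_equals_exhaustive_enumeration(trial, slack):
    """On every instance with <= 4 segments the DP optimum must match a
    brute-force search over all feasible boundary combinations."""
    rng = np.random.default_rng(100 + trial)
    n = 30
    y = rng.normal(size=n).cumsum()
    ref = rng.normal(size=n).cumsum()
    block = make_block(y[None, :], np.arange(n, dtype=float))
    res = cow_align(block, ref, segment_length=10, slack=slack)
    best_score, best_bounds = cow_brute_force(y, ref, 10, slack)
    assert res.scores[0] == pytest.approx(best_score, abs=1e-9)


def test_cow_preserves_row_count_and_monotone_node_maps():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(5, 120)).cumsum(axis=1)
    block = make_block(X)
    res = cow_align(block, X.mean(axis=0), segment_length=30, slack=5)
    assert res.aligned.shape == X.shape
    for nm in res.node_maps:
        src = [s for _, s in nm]
        assert all(b > a for a, b in zip(src, src[1:]))
        assert nm[0] == (0, 0) and nm[-1][1] == 119


def test_cow_rejects_bad_reference_and_infeasible_slack():
    block = make_block(np.zeros((2, 100)))
    with pytest.raises(ValueError, match="reference length"):
        cow_align(block, np.zeros(50), 20, 3)
    with pytest.raises(ValueError, match="segment_length"):
        cow_align(block, np.zeros(100), 10, 10)  # 10 < 2*10 + 3


def test_cow_zero_variance_segment_scores_zero():
    x = np.arange(60, dtype=float)
    flat = np.zeros(60)
    block = make_block(flat[None, :], x)
    res = cow_align(block, flat, segment_length=20, slack=2)
    assert res.scores[0] == pytest.approx(0.0)
    assert all(t == s for t, s in res.node_maps[0])  # ties prefer identity


# ---------------------------------------------------------------------------
# downsampling / derivative / band removal
# ---------------------------------------------------------------------------

def test_downsample_keeps_one_point_in_three():
    block = make_block(np.arange(7201, dtype=float)[None, :])
    out = downsample_every_k(block, 3)
    assert out.n_variables == 2401
    block9 = make_block(np.arange(9, dtype=float)[None, :])
    out9 = downsample_every_k(block9, 3)
    np.testing.assert_array_equal(out9.axis, [0, 3, 6])
    same = downsample_every_k(block9, 1)
    np.testing.assert_array_equal(same.values, block9.values)
    with pytest.raises(ValueError):
        downsample_every_k(block9, 0)


def test_sg_second_derivative_widths_and_analytic_values():
    t = np.arange(2401, dtype=float)
    block = make_block((t ** 2)[None, :], t)
    out = sg_second_derivative(block, window=15, polyorder=2)
    assert out.n_variables == 2387
    np.testing.assert_allclose(out.values, 2.0, atol=1e-8)
    linear = make_block((3.0 * t + 1)[None, :], t)
    np.testing.assert_allclose(
        sg_second_derivative(linear).values, 0.0, atol=1e-8)


def test_sg_second_derivative_is_linear_in_row_scaling():
    rng = np.random.default_rng(1)
    block = make_block(rng.normal(size=(3, 80)))
    scaled = make_block(4.5 * block.values)
    np.testing.assert_allclose(sg_second_derivative(scaled).values,
                               4.5 * sg_second_derivative(block).values,
                               rtol=1e-10)


def test_sg_second_derivative_input_validation():
    block = make_block(np.zeros((1, 10)))
    with pytest.raises(ValueError, match="odd"):
        sg_second_derivative(block, window=8)
    with pytest.raises(ValueError, match="width"):
        sg_second_derivative(block, window=15)


def test_remove_bands_inclusive_membership():
    block = make_block(np.zeros((1, 9)), axis=np.arange(1.0, 10.0))
    unchanged = remove_bands(block, [(10, 20)])
    np.testing.assert_array_equal(unchanged.axis, block.axis)

    five = make_block(np.zeros((1, 5)), axis=np.array([1.0, 2, 3, 4, 5]))
    out = remove_bands(five, [(2, 4)])
    np.testing.assert_array_equal(out.axis, [1.0, 5.0])

    axis = np.linspace(650, 4000, 10)
    ten = make_block(np.arange(10, dtype=float)[None, :], axis)
    out = remove_bands(ten, [(1750, 2670), (3700, 4000)])
    keep = [v for v in axis
            if not (1750 <= v <= 2670) and not (3700 <= v <= 4000)]
    np.testing.assert_allclose(out.axis, keep)


def test_remove_bands_is_idempotent():
    axis = np.linspace(650, 4000, 101)
    rng = np.random.default_rng(2)
    block = make_block(rng.normal(size=(2, 101)), axis, kind="wavenumber")
    once = remove_bands(block)
    twice = remove_bands(once)
    np.testing.assert_array_equal(once.values, twice.values)


# ---------------------------------------------------------------------------
# full chains
# ---------------------------------------------------------------------------

def test_full_lc_chain_yields_2387_columns(lc_full_scale_pretreated):
    raw, processed = lc_full_scale_pretreated
    assert raw.n_variables == 7201
    assert processed.n_variables == 2387


def test_ftir_chain_removes_bands_after_derivative():
    cfg = default_design(n_per_class=2, ftir_points=433, seed=5)
    block, _ = generate_block(cfg, "ftir")
    chain = pretreat_ftir(block)
    manual = remove_bands(sg_second_derivative(block))
    np.testing.assert_array_equal(chain.values, manual.values)
    assert not np.any((chain.axis >= 1750) & (chain.axis <= 2670))
    assert not np.any((chain.axis >= 3700) & (chain.axis <= 4000))


def test_lc_chain_improves_pairwise_correlation_of_shifted_samples():
    cfg = default_design(n_per_class=4, lc_points=721, seed=6,
                         noise_sd=0.0, baseline_amp=0.0, shift_sd=4.0,
                         height_jitter=0.0, latent_sd=0.0)
    block, truth = generate_block(cfg, "lc")
    assert np.ptp(truth.true_shifts) > 0

    def mean_within_class_corr(M):
        vals = []
        for c in range(5):  # within-class pairs: samples differ by shift only
            C = np.corrcoef(M[4 * c:4 * (c + 1)])
            iu = np.triu_indices_from(C, k=1)
            vals.append(C[iu].mean())
        return np.mean(vals)

    before = mean_within_class_corr(block.values)
    after = mean_within_class_corr(pretreat_lc(block).values)
    assert after >= before


def test_pretreat_checks_axis_kind():
    lc = make_block(np.zeros((2, 100)))
    with pytest.raises(ValueError, match="wavenumber"):
        pretreat_ftir(lc)
    ftir = make_block(np.zeros((2, 100)), axis=np.linspace(650, 4000, 100),
                      kind="wavenumber")
    with pytest.raises(ValueError, match="retention_time"):
        pretreat_lc(ftir)
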