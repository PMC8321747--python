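"""Fusion strategies: concatenation bookkeeping, fuzzy connectives, and
the majority-vote decision rule."""

import itertools

import numpy as np
import pytest

from chemfuse import (MembershipMatrix, fuzzy_aggregate, high_level_decide,
                      low_level_fuse, mid_level_fuse)
from helpers import make_block


def memb(rows, order=("Class1", "Class2")):
    return MembershipMatrix(np.atleast_2d(np.asarray(rows, float)),
                            list(order))


# ---------------------------------------------------------------------------
# low / mid level
# ---------------------------------------------------------------------------

def test_low_level_width_is_sum_of_block_widths():
    rng = np.random.default_rng(0)
    a = make_block(rng.normal(size=(3, 2387)))
    b = make_block(rng.normal(size=(3, 1097)))
    fused = low_level_fuse([a, b])
    assert fused.n_variables == 3484
    assert fused.sample_ids == a.sample_ids


def test_low_level_single_block_is_identity():
    a = make_block(np.random.default_rng(1).normal(size=(4, 7)))
    assert low_level_fuse([a]) is a


def test_low_level_preserves_column_order_without_scaling():
    blocks = [make_block(np.full((2, w), float(w))) for w in (2, 3, 4)]
    fused = low_level_fuse(blocks, scale=False)
    assert fused.n_variables == 9
    np.testing.assert_array_equal(fused.values[0],
                                  [2, 2, 3, 3, 3, 4, 4, 4, 4])


def test_low_level_rejects_mismatched_samples():
    a = make_block(np.zeros((3, 2)))
    b = make_block(np.zeros((4, 2)))
    with pytest.raises(ValueError):
        low_level_fuse([a, b])


def test_mid_level_concatenates_feature_counts():
    F = mid_level_fuse([np.zeros((5, 10)), np.zeros((5, 9))])
    assert F.shape == (5, 19)
    a, b = np.zeros((5, 3)), np.zeros((5, 4))
    assert mid_level_fuse([a, b]).shape == (5, 7)


def test_mid_level_empty_selection_passes_other_block_through():
    with pytest.warns(UserWarning, match="no features"):
        F = mid_level_fuse([np.zeros((5, 0)), np.ones((5, 4))])
    assert F.shape == (5, 4)
    with pytest.raises(ValueError):
        mid_level_fuse([np.zeros((5, 0)), np.zeros((5, 0))])


# ---------------------------------------------------------------------------
# fuzzy connectives
# ---------------------------------------------------------------------------

def test_product_connective_arithmetic():
    out = fuzzy_aggregate([memb([0.9, 0.1]), memb([0.8, 0.2])], "product")
    np.testing.assert_allclose(out.values, [[0.72, 0.02]])


def test_identical_inputs_keep_their_argmax_under_every_operator():
    m = memb([0.7, 0.3])
    for op in ("maximum", "minimum", "average"):
        np.testing.assert_allclose(
            fuzzy_aggregate([m, m], op).values, m.values)
    prod = fuzzy_aggregate([m, m], "product")
    np.testing.assert_allclose(prod.values, m.values ** 2)
    assert prod.hard_classes()[0] == m.hard_classes()[0]


def test_operators_are_commutative_in_the_block_list():
    rng = np.random.default_rng(2)
    ms = [memb(rng.uniform(size=(4, 2))) for _ in range(3)]
    for op in ("maximum", "minimum", "average", "product"):
        base = fuzzy_aggregate(ms, op).values
        for perm in itertools.permutations(ms):
            np.testing.assert_allclose(
                fuzzy_aggregate(list(perm), op).values, base)


def test_operator_outputs_stay_in_unit_interval():
    rng = np.random.default_rng(3)
    ms = [memb(rng.uniform(size=(6, 2))) for _ in range(2)]
    for op in ("maximum", "minimum", "average", "product"):
        v = fuzzy_aggregate(ms, op).values
        assert v.min() >= 0.0 and v.max() <= 1.0


def test_class_order_mismatch_rejected():
    with pytest.raises(ValueError, match="class_order"):
        fuzzy_aggregate([memb([0.5, 0.5]),
                         memb([0.5, 0.5], order=("Class2", "Class1"))],
                        "average")


def test_unknown_operator_rejected():
    with pytest.raises(ValueError, match="operator"):
        fuzzy_aggregate([memb([1.0, 0.0])], "median")


# ---------------------------------------------------------------------------
# high-level decision
# ---------------------------------------------------------------------------

def test_blocks_disagree_but_dominant_memberships_win():
    # one block votes Class1 firmly; the other votes Class2 narrowly while
    # still granting Class1 a high degree -> fused decision must be Class1
    ftir = memb([0.95, 0.30])           # argmax Class1
    lc = memb([0.80, 0.90])             # argmax Class2
    dec = high_level_decide([ftir, lc])
    assert dec.final_class[0] == "Class1"
    assert dec.per_operator_class["maximum"][0] == "Class1"


def test_unanimous_blocks_are_always_preserved():
    rng = np.random.default_rng(4)
    order = ["Class1", "Class2", "Class3"]
    for _ in range(20):
        a = rng.uniform(size=3)
        b = rng.uniform(size=3)
        k = rng.integers(3)
        a[k] = 1.0
        b[k] = 1.0
        a[np.arange(3) != k] *= 0.9  # strict argmax at k in both blocks
        b[np.arange(3) != k] *= 0.9
        dec = high_level_decide([memb(a, order), memb(b, order)])
        assert dec.final_class[0] == order[k]
        for op in dec.per_operator_class.values():
            assert op[0] == order[k]


def test_exact_opposition_resolves_deterministically():
    dec = high_level_decide([memb([1.0, 0.0]), memb([0.0, 1.0])])
    # every connective yields a symmetric row; argmax falls back to class
    # order, so the first class wins everywhere
    assert dec.final_class[0] == "Class1"
    again = high_level_decide([memb([1.0, 0.0]), memb([0.0, 1.0])])
    assert again.final_class[0] == dec.final_class[0]


def test_two_two_operator_tie_broken_by_average_membership():
    order = ["A", "B", "C"]
    b1 = memb([0.95, 0.0, 0.5], order)
    b2 = memb([0.15, 0.0, 0.5], order)
    dec = high_level_decide([b1, b2])
    votes = {op: dec.per_operator_class[op][0]
             for op in dec.per_operator_class}
    assert sorted(votes.values()).count("A") == 2  # max & average
    assert sorted(votes.values()).count("C") == 2  # min & product
    assert dec.final_class[0] == "A"  # average membership 0.55 > 0.5


def test_high_level_needs_at_least_two_blocks():
    with pytest.raises(ValueError):
        high_level_decide([memb([1.0, 0.0])])
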