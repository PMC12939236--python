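"""Loss-formula oracles and invariants of the composite objective."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adstage.nn import Tensor
from adstage.objectives import (LossBreakdown, LossWeights, consistency_loss,
                                cross_entropy, ordinal_loss, total_loss)

RNG = np.random.default_rng(42)


def softmax(z):
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def brute_force_ordinal(logits, y):
    """Independent oracle: expectation arithmetic per sample, then mean."""
    p = softmax(np.asarray(logits, float))
    vals = []
    for row, yi in zip(p, y):
        s_hat = sum(c * row[c] for c in range(len(row)))
        vals.append((s_hat - yi) ** 2)
    return float(np.mean(vals))


def logits_for(p):
    """Logits whose softmax approximates the target point mass."""
    return np.log(np.clip(p, 1e-12, 1.0))


# -- ordinal loss ----------------------------------------------------------

def test_point_mass_on_true_class_gives_zero():
    logits = logits_for(np.array([[1, 0, 0, 0]], float))
    assert ordinal_loss(logits, [0]) == pytest.approx(0.0, abs=1e-9)


def test_uniform_distribution_expectation():
    logits = np.zeros((1, 4))
    # s_hat = (0+1+2+3)/4 = 1.5 -> (1.5 - 0)^2 = 2.25
    assert ordinal_loss(logits, [0]) == pytest.approx(2.25, abs=1e-12)


def test_distant_confidence_penalized_quadratically():
    far = logits_for(np.array([[0, 0, 0, 1]], float))
    near = logits_for(np.array([[0, 1, 0, 0]], float))
    assert ordinal_loss(far, [0]) == pytest.approx(9.0, abs=1e-6)
    assert ordinal_loss(near, [0]) == pytest.approx(1.0, abs=1e-6)


def test_point_mass_grid_matches_squared_distance():
    for k in range(4):
        for y in range(4):
            p = np.zeros((1, 4))
            p[0, k] = 1.0
            got = ordinal_loss(logits_for(p), [y])
            assert got == pytest.approx((k - y) ** 2, abs=1e-6)


def test_ordinal_matches_brute_force_on_random_batches():
    for _ in range(100):
        logits = RNG.normal(size=(8, 4)) * 3
        y = RNG.integers(0, 4, size=8)
        assert ordinal_loss(logits, y) == pytest.approx(
            brute_force_ordinal(logits, y), abs=1e-9)


@given(st.floats(-50, 50))
@settings(max_examples=30, deadline=None)
def test_ordinal_invariant_to_logit_shift(shift):
    logits = np.array([[0.3, -1.2, 2.0, 0.5], [1.0, 1.0, -2.0, 0.0]])
    y = [2, 1]
    assert ordinal_loss(logits + shift, y) == pytest.approx(
        ordinal_loss(logits, y), abs=1e-8)


def test_ordinal_label_out_of_range_raises():
    with pytest.raises(ValueError):
        ordinal_loss(np.zeros((1, 4)), [4])


# -- consistency loss ------------------------------------------------------

def test_consistency_zero_iff_views_match():
    p = softmax(RNG.normal(size=(5, 4)))
    assert consistency_loss(p, p) == 0.0
    q = softmax(RNG.normal(size=(5, 4)))
    assert consistency_loss(p, q) > 0.0


def test_consistency_disjoint_point_masses():
    p = np.array([[1.0, 0, 0, 0]])
    q = np.array([[0, 1.0, 0, 0]])
    assert consistency_loss(p, q) == pytest.approx(2.0, abs=1e-12)


def test_consistency_symmetric():
    p = softmax(RNG.normal(size=(6, 4)))
    q = softmax(RNG.normal(size=(6, 4)))
    assert consistency_loss(p, q) == pytest.approx(consistency_loss(q, p),
                                                   abs=1e-12)


def test_consistency_rejects_unnormalized_rows():
    p = np.full((2, 4), 0.3)
    q = softmax(RNG.normal(size=(2, 4)))
    with pytest.raises(ValueError):
        consistency_loss(p, q)


# -- cross entropy ---------------------------------------------------------

def test_ce_uniform_logits_is_log4():
    assert cross_entropy(np.zeros((3, 4)), [0, 1, 3]) == pytest.approx(
        np.log(4), abs=1e-12)


def test_ce_confident_correct_approaches_zero():
    logits = np.array([[30.0, 0, 0, 0]])
    assert cross_entropy(logits, [0]) < 1e-9


def test_ce_matches_logsumexp_oracle_on_random_batches():
    for _ in range(100):
        logits = RNG.normal(size=(6, 4)) * 4
        y = RNG.integers(0, 4, size=6)
        lse = np.log(np.exp(logits).sum(axis=1))
        ref = float(np.mean(lse - logits[np.arange(6), y]))
        assert cross_entropy(logits, y) == pytest.approx(ref, abs=1e-9)


# -- total loss ------------------------------------------------------------

def test_zero_weights_reduce_to_ce():
    logits = RNG.normal(size=(4, 4))
    y = [0, 1, 2, 3]
    bd = total_loss(logits, RNG.normal(size=(4, 4)), y, LossWeights(0, 0))
    assert bd.total == pytest.approx(bd.ce, abs=1e-12)
    assert bd.total == pytest.approx(cross_entropy(logits, y), abs=1e-12)


def test_default_weights_match_hand_composition():
    logits = np.array([[2.0, 0.1, -1.0, 0.3], [-0.5, 1.5, 0.2, 0.0]])
    logits_t = np.array([[1.5, 0.2, -0.8, 0.1], [-0.2, 1.0, 0.5, 0.3]])
    y = [0, 1]
    bd = total_loss(logits, logits_t, y)
    hand = (cross_entropy(logits, y) + 0.3 * ordinal_loss(logits, y)
            + 0.2 * consistency_loss(softmax(logits), softmax(logits_t)))
    assert bd.total == pytest.approx(hand, abs=1e-9)
    assert bd.total == pytest.approx(
        bd.ce + 0.3 * bd.ordinal + 0.2 * bd.consistency, abs=1e-6)


def test_identical_views_drop_consistency_term():
    logits = RNG.normal(size=(3, 4))
    y = [0, 2, 3]
    bd = total_loss(logits, logits, y)
    assert bd.consistency == 0.0
    assert bd.total == pytest.approx(bd.ce + 0.3 * bd.ordinal, abs=1e-12)


def test_all_terms_nonnegative_and_total_monotone():
    for _ in range(20):
        bd = total_loss(RNG.normal(size=(5, 4)), RNG.normal(size=(5, 4)),
                        RNG.integers(0, 4, size=5))
        assert bd.ce >= 0 and bd.ordinal >= 0 and bd.consistency >= 0
    # raising a sub-loss weight cannot lower the total
    logits, logits_t = RNG.normal(size=(5, 4)), RNG.normal(size=(5, 4))
    y = RNG.integers(0, 4, size=5)
    t1 = total_loss(logits, logits_t, y, LossWeights(0.3, 0.2)).total
    t2 = total_loss(logits, logits_t, y, LossWeights(0.5, 0.2)).total
    assert t2 >= t1


def test_mismatched_batches_rejected():
    with pytest.raises(ValueError):
        total_loss(np.zeros((2, 4)), np.zeros((3, 4)), [0, 1])


def test_negative_weights_rejected():
    with pytest.raises(ValueError):
        LossWeights(-0.1, 0.2)


def test_losses_differentiable_through_tensors():
    logits = Tensor(RNG.normal(size=(4, 4)), requires_grad=True)
    loss = ordinal_loss(logits, [0, 1, 2, 3])
    assert isinstance(loss, Tensor)
    loss.backward()
    assert logits.grad is not None and np.abs(logits.grad).max() > 0
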