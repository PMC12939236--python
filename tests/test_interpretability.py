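"""Token-importance machinery: norms, overlays, concentration, trends."""

import numpy as np
import pytest

from adstage.interpretability import (ImportanceMap, classwise_mean_maps,
                                      concentration_score, overlay,
                                      rank_stability,
                                      stage_concentration_trend,
                                      token_importance)

RNG = np.random.default_rng(5)


def make_map(norms, true_stage=0):
    t2 = np.zeros((16, 8))
    t2[:, 0] = norms
    return token_importance(t2, true_stage=true_stage)


def test_raw_norms_match_sum_of_squares_oracle():
    t2 = RNG.normal(size=(16, 64))
    imap = token_importance(t2)
    ref = np.array([np.sqrt(sum(v * v for v in row)) for row in t2])
    assert np.allclose(imap.raw_norms, ref, atol=1e-6)


def test_identical_rows_give_all_ones_grid():
    t2 = np.tile(RNG.normal(size=64), (16, 1))
    assert np.all(token_importance(t2).grid == 1.0)


def test_doubled_row_is_unique_maximum():
    v = RNG.normal(size=32)
    t2 = np.tile(v, (16, 1))
    t2[5] = 2 * v
    grid = token_importance(t2).grid.ravel()
    assert grid[5] == 1.0
    assert np.all(grid[np.arange(16) != 5] < 1.0)


def test_grid_invariant_to_positive_scaling():
    t2 = RNG.normal(size=(16, 32))
    a = token_importance(t2).grid
    b = token_importance(7.3 * t2).grid
    assert np.allclose(a, b, atol=1e-10)


def test_row_major_grid_convention():
    t2 = np.ones((16, 4)) * 0.1
    t2[6] = 10.0          # token 6 -> grid cell (1, 2)
    imap = token_importance(t2)
    assert imap.grid[1, 2] == 1.0


def test_nonfinite_embeddings_rejected():
    t2 = np.ones((16, 4))
    t2[0, 0] = np.nan
    with pytest.raises(ValueError):
        token_importance(t2)


def test_overlay_dimensions_and_hot_corner(tmp_path):
    img = np.zeros((64, 64))
    t2 = np.ones((16, 4)) * 0.01
    t2[0] = 5.0           # cell (0,0): top-left quadrant-of-16 hottest
    imap = token_importance(t2)
    out = overlay(imap, img, tmp_path / "o.png")
    assert out.shape == (64, 64, 3)
    assert (tmp_path / "o.png").exists()
    # warm colormap: red channel strongest where the grid is hot
    red = out[..., 0].astype(float)
    assert red[:16, :16].mean() > red[-16:, -16:].mean()
    uniform = overlay(token_importance(np.ones((16, 4))), img)
    assert np.ptp(uniform.reshape(-1, 3), axis=0).max() <= 1  # constant tint


def test_overlay_requires_2d_image():
    with pytest.raises(ValueError):
        overlay(token_importance(np.ones((16, 4))), np.zeros((4, 4, 3)))


def test_classwise_mean_maps_bounds_and_single_slice():
    maps = [make_map(RNG.random(16), true_stage=s % 4) for s in range(8)]
    means = classwise_mean_maps(maps)
    assert set(means) == {0, 1, 2, 3}
    for g in means.values():
        assert g.min() >= 0 and g.max() <= 1
    solo = [m for m in maps if m.true_stage == 0][0]
    only = classwise_mean_maps([solo])
    assert np.array_equal(only[0], solo.grid)


def test_rank_stability_nonincreasing_and_brute_force():
    maps = [make_map(RNG.random(16) + 0.1) for _ in range(50)]
    rs = rank_stability(maps)
    assert np.all(np.diff(rs["rank_mean"]) <= 1e-12)
    flat = np.stack([m.grid.ravel() for m in maps])
    order = np.argsort(-flat.mean(axis=0), kind="stable")
    assert np.allclose(rs["rank_mean"], flat[:, order].mean(axis=0))
    assert np.allclose(rs["rank_std"], flat[:, order].std(axis=0))
    same = [maps[0]] * 3
    assert np.allclose(rank_stability(same)["rank_std"], 0.0)


def test_concentration_uniform_and_degenerate():
    uni = make_map(np.ones(16))
    assert concentration_score(uni, 4) == pytest.approx(0.25)
    assert concentration_score(uni, 16) == pytest.approx(1.0)
    single = make_map(np.eye(16)[3] * 5)
    for k in (1, 4, 16):
        assert concentration_score(single, k) == pytest.approx(1.0)


def test_concentration_monotone_in_k_and_reorder_invariant():
    norms = RNG.random(16) + 0.05
    m = make_map(norms)
    scores = [concentration_score(m, k) for k in range(1, 17)]
    assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))
    assert scores[-1] == pytest.approx(1.0)
    perm = make_map(norms[RNG.permutation(16)])
    assert concentration_score(perm, 4) == pytest.approx(
        concentration_score(m, 4))


def test_concentration_zero_norms_signaled():
    with pytest.raises(ValueError):
        concentration_score(make_map(np.zeros(16)), 4)


def test_stage_trend_perfect_monotone_gives_rho_one():
    maps = []
    for s in range(4):
        for _ in range(5):
            norms = np.ones(16)
            norms[:4] += 2.0 * s + 1.0    # concentration grows with stage
            maps.append(make_map(norms, true_stage=s))
    prof = stage_concentration_trend(maps, k=4)
    assert prof.stage_correlation == pytest.approx(1.0)
    assert np.all(np.diff(prof.per_stage_mean) > 0)


def test_stage_trend_independent_scores_near_zero():
    maps = [make_map(RNG.random(16) + 0.2, true_stage=int(s))
            for s in RNG.integers(0, 4, 800)]
    prof = stage_concentration_trend(maps, k=4)
    assert abs(prof.stage_correlation) < 0.1


def test_stage_trend_hand_averaged_fixture():
    maps = [make_map(np.array([4.0] + [1.0] * 15), 0),
            make_map(np.array([6.0] + [1.0] * 15), 0),
            make_map(np.array([8.0] + [1.0] * 15), 1),
            make_map(np.array([10.0] + [1.0] * 15), 1)]
    prof = stage_concentration_trend(maps, k=1)
    assert prof.per_stage_mean[0] == pytest.approx((4 / 19 + 6 / 21) / 2)
    assert prof.per_stage_mean[1] == pytest.approx((8 / 23 + 10 / 25) / 2)


def test_stage_trend_degenerate_inputs_signaled():
    with pytest.raises(ValueError):            # one stage only
        stage_concentration_trend([make_map(RNG.random(16), 0)] * 3)
    const = [make_map(np.ones(16), s) for s in (0, 1, 2, 3)]
    with pytest.raises(ValueError):            # constant scores
        stage_concentration_trend(const)
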