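"""Salience maps: epistemic value, enhancement, centre-surround sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage, signal

from epigaze import salience_map as sm
from epigaze import scene_kinematics as sk
from epigaze.hypothesis_inference import BeliefState, sigma_from_entropy


def make_belief(p_big, t=1):
    from epigaze.hypothesis_inference import binary_entropy

    p = np.array([1.0 - p_big, p_big])
    h = binary_entropy(p)
    return BeliefState(shape_posterior=p.copy(), full_posterior=p, t=t,
                       entropy_full=h, sigma_obj=sigma_from_entropy(h))


def random_fixture(rng, res=32):
    layout = sk.make_layout(int(rng.integers(1, 5)), seed=int(rng.integers(10)))
    belief = make_belief(float(rng.uniform(0.05, 0.95)))
    hand_pred = {g: rng.uniform(0.2, 0.8, 2) for g in ("SMALL", "BIG")}
    shape_pred = {
        g: sk.ANGLE_TEMPLATES[c] + rng.normal(0, 5, 16)
        for g, c in (("SMALL", "PRE"), ("BIG", "POW"))
    }
    return belief, hand_pred, shape_pred, layout, res


def brute_force_epistemic(belief, hand_pred, shape_pred, layout, res):
    """Independent oracle: expected posterior-entropy reduction computed by
    explicit loops over hypotheses and the 6-symbol alphabet."""
    p = sm.emission_probs(hand_pred, shape_pred, layout, res)
    w = belief.full_posterior
    out = np.zeros((res, res))
    for i in range(res):
        for j in range(res):
            h_prior = -sum(wg * np.log2(wg) for wg in w if wg > 0)
            exp_post = 0.0
            for o in range(len(sm.SYMBOLS)):
                po = w[0] * p[0, o, i, j] + w[1] * p[1, o, i, j]
                if po <= 0:
                    continue
                post = np.array([w[0] * p[0, o, i, j],
                                 w[1] * p[1, o, i, j]]) / po
                h_post = -sum(q * np.log2(q) for q in post if q > 0)
                exp_post += po * h_post
            out[i, j] = h_prior - exp_post
    return out


class TestEpistemicValue:
    def test_matches_brute_force_mutual_information(self):
        """The vectorized epistemic map equals the loop-based expected
        entropy reduction to 1e-9 on 20 random fixtures."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            belief, hand_pred, shape_pred, layout, res = random_fixture(rng)
            fast = sm.epistemic_value_map(belief, hand_pred, shape_pred,
                                          layout, res)
            slow = brute_force_epistemic(belief, hand_pred, shape_pred,
                                         layout, res)
            assert np.max(np.abs(fast - slow)) < 1e-9

    def test_bounded_by_posterior_entropy(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            belief, hand_pred, shape_pred, layout, res = random_fixture(rng)
            S = sm.epistemic_value_map(belief, hand_pred, shape_pred,
                                       layout, res)
            assert np.all(S >= 0)
            assert np.all(S <= belief.entropy_full + 1e-12)

    def test_zero_under_certainty(self):
        rng = np.random.default_rng(2)
        _, hand_pred, shape_pred, layout, res = random_fixture(rng)
        S = sm.epistemic_value_map(make_belief(1.0), hand_pred, shape_pred,
                                   layout, res)
        assert np.all(S == 0.0)

    def test_informative_hand_location_approaches_full_bit(self):
        """With a flat posterior and coincident hand predictions whose
        configurations differ, the fixation on the predicted hand resolves
        most of the 1-bit uncertainty."""
        layout = sk.make_layout(1, 0)
        hand = np.array([0.5, 0.6])
        hand_pred = {"SMALL": hand, "BIG": hand}
        shape_pred = {"SMALL": sk.ANGLE_TEMPLATES["PRE"],
                      "BIG": sk.ANGLE_TEMPLATES["POW"]}
        S = sm.epistemic_value_map(make_belief(0.5), hand_pred, shape_pred,
                                   layout, 64)
        r, c = int(hand[1] * 64), int(hand[0] * 64)
        assert S[r, c] > 0.3
        assert S[r, c] == pytest.approx(S.max())


class TestDifferentialSalience:
    def test_constant_map_becomes_zero(self):
        assert np.all(sm.differential_salience(np.full((8, 8), 3.2)) == 0.0)

    def test_shift_and_argmax_preservation(self):
        rng = np.random.default_rng(3)
        S = rng.uniform(0.2, 1.0, (16, 16))
        Sk = sm.differential_salience(S)
        assert Sk.min() == 0.0
        assert np.argmax(Sk) == np.argmax(S)
        np.testing.assert_allclose(Sk, S - S.min())

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            sm.differential_salience(np.array([[1.0, np.inf]]))


class TestComponentEnhancement:
    def test_single_unit_bump(self):
        c = np.array([[0.5, 0.5], [0, 0], [0, 0], [0, 0]])
        R = sm.component_enhancement(c, np.array([1.0, 0, 0, 0]), None,
                                     res=64)
        r, col = np.unravel_index(np.argmax(R), R.shape)
        assert R.max() == pytest.approx(1.0, abs=0.02)
        assert abs((col + 0.5) / 64 - 0.5) < 0.02
        assert np.all(R >= 0)

    def test_geometric_accumulation_to_twice_the_stationary_sum(self):
        """With decay 1/2 and frozen components, R_k converges to twice the
        per-step component sum and the residual halves each step."""
        c = np.array([[0.3, 0.3], [0.7, 0.7], [0.2, 0.8], [0.8, 0.2]])
        w = np.array([0.4, 0.6, 0.3, 0.7])
        base = sm.component_enhancement(c, w, None, res=32, decay_a=0.5)
        R = None
        residuals = []
        for _ in range(12):
            R = sm.component_enhancement(c, w, R, res=32, decay_a=0.5)
            residuals.append(np.max(np.abs(R - 2.0 * base)))
        assert residuals[-1] < 1e-3
        ratios = [b / a for a, b in zip(residuals, residuals[1:]) if a > 1e-12]
        np.testing.assert_allclose(ratios, 0.5, atol=1e-6)

    def test_decay_is_a_contraction(self):
        c = np.array([[0.3, 0.3], [0.7, 0.7], [0.2, 0.8], [0.8, 0.2]])
        w = np.array([1.0, 0.5, 0.25, 0.75])
        R_prev, diffs = None, []
        last = np.zeros((32, 32))
        for _ in range(8):
            R = sm.component_enhancement(c, w, R_prev, res=32, decay_a=0.5)
            diffs.append(np.linalg.norm(R - last))
            last, R_prev = R, R
        assert all(a > b for a, b in zip(diffs[1:], diffs[2:]))

    def test_invalid_decay_rejected(self):
        with pytest.raises(ValueError, match="decay"):
            sm.component_enhancement(np.zeros((4, 2)), np.ones(4), None,
                                     decay_a=1.0)


class TestObjectWeights:
    def test_peak_at_object_and_tail_far_away(self):
        layout = sk.make_layout(1, 0)
        b = make_belief(0.5)
        at_obj = sm.object_weights(b, layout.big_pos, layout, sigma_obj=0.1)
        far = sm.object_weights(b, layout.big_pos + np.array([0.0, 0.5]),
                                layout, sigma_obj=0.1)
        assert at_obj[1] == pytest.approx(0.5)       # posterior x peak 1
        assert far[1] < 1e-4
    def test_monotone_in_hand_object_distance(self):
        layout = sk.make_layout(1, 0)
        b = make_belief(0.5)
        d = layout.big_pos - np.array([0.5, 0.8])
        near = layout.big_pos - 0.2 * d
        mid = layout.big_pos - 0.5 * d
        w_near = sm.object_weights(b, near, layout, sigma_obj=0.2)
        w_mid = sm.object_weights(b, mid, layout, sigma_obj=0.2)
        assert w_near[1] > w_mid[1]


class TestComposeAndDownsample:
    def test_compose_identities(self):
        S = np.random.default_rng(0).uniform(0, 1, (32, 32))
        np.testing.assert_array_equal(sm.compose_enhanced(S, np.zeros_like(S)),
                                      S)
        np.testing.assert_array_equal(sm.compose_enhanced(np.zeros_like(S), S),
                                      S)
        with pytest.raises(ValueError, match="mismatch"):
            sm.compose_enhanced(S, np.zeros((16, 16)))

    def test_dominant_bump_can_move_the_argmax(self):
        S_k = sm.gaussian_bump(np.array([0.2, 0.2]), 0.05, 64) * 0.4
        R_k = sm.gaussian_bump(np.array([0.8, 0.8]), 0.05, 64) * 1.5
        combined = sm.compose_enhanced(S_k, R_k)
        assert np.argmax(combined) != np.argmax(S_k)

    def test_coarse_grid_has_256_cells(self):
        out = sm.downsample_center_surround(np.random.default_rng(1)
                                            .uniform(0, 1, (128, 128)))
        assert out.shape == (16, 16)
        assert out.size == 256

    def test_constant_input_cancels_exactly(self):
        out = sm.downsample_center_surround(np.full((64, 64), 0.7))
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_matches_direct_difference_of_gaussians_convolution(self):
        """The ndimage-based DoG equals an independent convolution with
        explicitly constructed Gaussian kernels (symmetric boundary)."""
        rng = np.random.default_rng(4)
        full = rng.uniform(0, 1, (64, 64))
        got = sm.downsample_center_surround(full, grid=16)

        def kern(sigma):
            radius = int(4.0 * sigma + 0.5)
            x = np.arange(-radius, radius + 1)
            k = np.exp(-0.5 * (x / sigma) ** 2)
            return k / k.sum()

        def blur(img, sigma):
            k = kern(sigma)
            tmp = np.apply_along_axis(
                lambda row: signal.convolve(
                    np.pad(row, len(k) // 2, mode="symmetric"), k, "valid"
                ), 1, img)
            return np.apply_along_axis(
                lambda col: signal.convolve(
                    np.pad(col, len(k) // 2, mode="symmetric"), k, "valid"
                ), 0, tmp)

        cell = 64 // 16
        dog = np.clip(blur(full, cell / 2) - blur(full, cell), 0, None)
        ref = dog.reshape(16, cell, 16, cell).mean(axis=(1, 3))
        np.testing.assert_allclose(got, ref, atol=1e-10)

    def test_point_source_gives_rectified_centre_response(self):
        full = np.zeros((64, 64))
        full[32, 32] = 1.0
        out = sm.downsample_center_surround(full)
        assert out[8, 8] > 0
        assert np.all(out >= 0)

    def test_indivisible_resolution_rejected(self):
        with pytest.raises(ValueError, match="tiling"):
            sm.downsample_center_surround(np.zeros((60, 60)))


class TestBayesianModelAverageSymmetry:
    def test_swapping_hypothesis_labels_permutes_nothing_observable(self):
        """Relabelling SMALL<->BIG together with their predictions, the
        posterior and the object positions leaves the combined map
        unchanged (the map is a Bayesian model average)."""
        rng = np.random.default_rng(5)
        belief, hand_pred, shape_pred, layout, _ = random_fixture(rng, res=64)
        grid_a = sm.build_salience_grid(
            belief, hand_pred, shape_pred, np.array([0.5, 0.55]),
            layout, None, 1, res=64,
        )
        swapped_belief = BeliefState(
            shape_posterior=belief.shape_posterior[::-1].copy(),
            full_posterior=belief.full_posterior[::-1].copy(),
            t=belief.t, entropy_full=belief.entropy_full,
            sigma_obj=belief.sigma_obj,
        )
        swapped_layout = sk.SceneLayout(
            big_pos=layout.small_pos, small_pos=layout.big_pos,
            start_pos=layout.start_pos, layout_id=layout.layout_id,
        )
        grid_b = sm.build_salience_grid(
            swapped_belief,
            {"SMALL": hand_pred["BIG"], "BIG": hand_pred["SMALL"]},
            {"SMALL": shape_pred["BIG"], "BIG": shape_pred["SMALL"]},
            np.array([0.5, 0.55]), swapped_layout, None, 1, res=64,
        )
        np.testing.assert_allclose(grid_a.full_res, grid_b.full_res,
                                   atol=1e-9)
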