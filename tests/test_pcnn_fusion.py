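import numpy as np
import pytest

from medfuse import DimensionError, PcnnParams, fuse_layer, normalize_feed, pcnn_firing_times, sts
from medfuse.filters import gradient_magnitude

from conftest import random_image
from oracles import pcnn_times_loop


def run_oracle(feed, beta, p: PcnnParams):
    return pcnn_times_loop(
        feed, beta, p.kernel, p.iterations, p.alpha_l, p.v_l, p.alpha_theta, p.v_theta, p.theta_init
    )


class TestSts:
    def test_constant_layer_has_zero_saliency(self):
        assert np.all(sts(np.full((8, 8), 0.3)) == 0)

    def test_step_edge_saliency_peaks_at_edge(self):
        layer = np.zeros((16, 16))
        layer[:, 8:] = 1.0
        beta = sts(layer)
        assert beta.max() == 1.0
        assert np.all(beta[:, [0, 1, 14, 15]] == 0)
        assert beta[:, 7:9].min() > 0.5

    def test_equals_rescaled_gradient_magnitude(self):
        layer = random_image(0, (8, 8)) - 0.5  # signed, like a residual layer
        g = gradient_magnitude(layer)
        np.testing.assert_allclose(sts(layer), g / g.max(), atol=1e-12)


class TestFiringTimes:
    def test_identical_dynamics_give_identical_times(self):
        feed = random_image(1, (6, 6))
        beta = sts(feed)
        t_a, t_b = pcnn_firing_times(feed, feed, beta, beta)
        np.testing.assert_array_equal(t_a, t_b)

    def test_zero_feed_never_fires(self):
        shape = (5, 5)
        t_a, t_b = pcnn_firing_times(
            np.ones(shape), np.zeros(shape), np.zeros(shape), np.zeros(shape)
        )
        assert np.all(t_a > 0)
        assert np.all(t_b == 0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scalar_simulation_oracle(self, seed):
        """Vectorized twin networks replicate a naive per-pixel, per-
        iteration simulation bit for bit."""
        rng = np.random.default_rng(seed)
        p = PcnnParams(iterations=50)
        feed_a = np.full((5, 5), 0.5)
        feed_a[2, 2] = 1.0
        feed_b = np.full((5, 5), 0.5)
        beta_a, beta_b = sts(feed_a), sts(feed_b)
        if seed > 0:  # widen coverage beyond the bright-pixel case
            feed_a, feed_b = rng.random((5, 5)), rng.random((5, 5))
            beta_a, beta_b = sts(feed_a), sts(feed_b)
        t_a, t_b = pcnn_firing_times(feed_a, feed_b, beta_a, beta_b, p)
        np.testing.assert_array_equal(t_a, run_oracle(feed_a, beta_a, p))
        np.testing.assert_array_equal(t_b, run_oracle(feed_b, beta_b, p))

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            pcnn_firing_times(np.zeros((4, 4)), np.zeros((4, 5)), np.zeros((4, 4)), np.zeros((4, 4)))


class TestFuseLayer:
    def test_equal_layers_fixed_point(self):
        layer = random_image(3, (8, 8))
        np.testing.assert_array_equal(fuse_layer(layer, layer), layer)

    def test_salient_patch_wins_over_flat_layer(self):
        """A textured bright patch out-fires a constant zero layer, so the
        patch pixels are copied from the non-flat side."""
        flat = np.zeros((12, 12))
        textured = np.zeros((12, 12))
        patch = (slice(4, 8), slice(4, 8))
        textured[patch] = 0.5 + 0.5 * random_image(4, (4, 4))
        fused = fuse_layer(flat, textured)
        np.testing.assert_array_equal(fused[patch], textured[patch])

    def test_every_pixel_comes_from_one_input(self):
        a = random_image(5, (10, 10))
        b = random_image(6, (10, 10))
        fused = fuse_layer(a, b)
        assert np.all((fused == a) | (fused == b))

    def test_swap_flips_selection_except_at_ties(self):
        a = random_image(7, (8, 8))
        b = random_image(8, (8, 8))
        t_a, t_b = pcnn_firing_times(normalize_feed(a), normalize_feed(b), sts(a), sts(b))
        fused_ab = fuse_layer(a, b)
        fused_ba = fuse_layer(b, a)
        ties = t_a == t_b
        np.testing.assert_array_equal(fused_ab[~ties], fused_ba[~ties])
        # at ties the first (MRI-slot) argument wins in both orderings
        np.testing.assert_array_equal(fused_ab[ties], a[ties])
        np.testing.assert_array_equal(fused_ba[ties], b[ties])

    def test_zero_saliency_reduces_to_uncoupled_threshold_decay(self):
        """With beta = 0 the linking field is inert: each neuron is an
        isolated threshold-decay unit, so its firing times are a function
        of its own feed value alone and match a 1-D scalar recurrence."""
        a = np.linspace(0, 1, 64).reshape(8, 8)
        b = 1.0 - a
        p = PcnnParams(iterations=60)
        t_a, t_b = pcnn_firing_times(a, b, np.zeros_like(a), np.zeros_like(b), p)

        def scalar_last_fire(feed: float) -> int:
            theta, last = p.theta_init, 0
            for n in range(1, p.iterations + 1):
                fired = feed >= theta
                if fired:
                    last = n
                theta = np.exp(-p.alpha_theta) * theta + p.v_theta * fired
            return last

        for t, feed in ((t_a, a), (t_b, b)):
            expected = np.vectorize(scalar_last_fire)(feed)
            np.testing.assert_array_equal(t, expected)
        assert scalar_last_fire(1.0) > 0 and scalar_last_fire(0.0) == 0

    def test_prefer_earlier_switch_changes_comparison(self):
        a = random_image(9, (8, 8))
        b = random_image(10, (8, 8))
        t_a, t_b = pcnn_firing_times(normalize_feed(a), normalize_feed(b), sts(a), sts(b))
        fused = fuse_layer(a, b, prefer_earlier=True)
        sel_a = t_a <= t_b
        np.testing.assert_array_equal(fused[sel_a], a[sel_a])
        np.testing.assert_array_equal(fused[~sel_a], b[~sel_a])


def test_params_validation():
    with pytest.raises(ValueError):
        PcnnParams(iterations=0)
    with pytest.raises(ValueError):
        PcnnParams(linking_kernel=((0.5, 1, 0.5), (1, 1, 1), (0.5, 1, 0.5)))
    with pytest.raises(ValueError):
        PcnnParams(linking_kernel=((0.5, -1, 0.5), (1, 0, 1), (0.5, 1, 0.5)))
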