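import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from salicaps.network import (
    ConfigurationError,
    LaneConfig,
    NetworkConfig,
    conv_lane,
    dynamic_routing,
    forward,
    hidden_caps,
    init_params,
    loss_and_grads,
    primary_caps,
    squash,
)
from oracles import conv1d_oracle, forward_oracle, routing_oracle, squash_oracle


class TestSquash:
    def test_zero_vector_maps_to_zero(self):
        np.testing.assert_array_equal(squash(np.zeros(16)), np.zeros(16))
        np.testing.assert_array_equal(
            squash(np.zeros(16), variant="as_printed"), np.zeros(16)
        )

    @pytest.mark.parametrize("variant", ["sabour", "as_printed"])
    def test_unit_norm_gives_half(self, variant):
        s = np.array([1.0, 0.0, 0.0])
        assert np.linalg.norm(squash(s, variant)) == pytest.approx(0.5, abs=1e-7)

    def test_norm_three_distinguishes_variants(self):
        s = np.array([3.0, 0.0])
        assert np.linalg.norm(squash(s, "sabour")) == pytest.approx(0.9, abs=1e-7)
        assert np.linalg.norm(squash(s, "as_printed")) == pytest.approx(
            0.3, abs=1e-7
        )

    @given(
        st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False),
            min_size=2, max_size=8,
        ),
        st.sampled_from(["sabour", "as_printed"]),
    )
    @settings(max_examples=100, deadline=None)
    def test_direction_preserved_and_norm_bounded(self, vec, variant):
        s = np.asarray(vec)
        v = squash(s, variant)
        # v is a nonnegative multiple of s
        assert np.all(v * s >= -1e-12)
        bound = 1.0 if variant == "sabour" else 0.5
        assert np.linalg.norm(v) <= bound + 1e-9

    def test_matches_oracle(self, rng):
        for variant in ("sabour", "as_printed"):
            s = rng.normal(0, 2, size=16)
            np.testing.assert_allclose(
                squash(s, variant), squash_oracle(s, variant), rtol=1e-7
            )


class TestConvLane:
    def test_zero_input_zero_output(self):
        cfg = LaneConfig(kernel_size=3, n_conv_filters=4)
        weights = np.ones((3, 20, 4))
        out = conv_lane(np.zeros((10, 20)), cfg, weights, np.zeros(4))
        np.testing.assert_array_equal(out, 0.0)

    def test_delta_kernel_reproduces_channel(self, rng):
        cfg = LaneConfig(kernel_size=1, n_conv_filters=1)
        weights = np.zeros((1, 20, 1))
        weights[0, 7, 0] = 2.0  # pick out channel 7, doubled
        x = rng.random((12, 20))
        out = conv_lane(x, cfg, weights, np.zeros(1))
        np.testing.assert_allclose(out[:, 0], 2.0 * x[:, 7], rtol=1e-12)

    def test_matches_triple_loop_oracle(self, rng):
        cfg = LaneConfig(kernel_size=3, n_conv_filters=5)
        x = rng.normal(size=(20, 20))
        weights = rng.normal(size=(3, 20, 5))
        bias = rng.normal(size=5)
        np.testing.assert_allclose(
            conv_lane(x, cfg, weights, bias),
            conv1d_oracle(x, weights, bias),
            rtol=1e-10, atol=1e-12,
        )

    def test_kernel_longer_than_input_rejected(self, rng):
        cfg = LaneConfig(kernel_size=33)
        with pytest.raises(ValueError, match="kernel_size"):
            conv_lane(rng.random((10, 20)), cfg, np.zeros((33, 20, 10)),
                      np.zeros(10))


class TestPrimaryCaps:
    def test_grid_size_default_config(self, rng):
        # stride 1 keeps one capsule grid position per input position
        cfg = LaneConfig(kernel_size=3)
        feats = rng.random((1, 50, 10))
        prim_W = rng.normal(size=(10, 8 * 16))
        mu = primary_caps(feats, cfg, prim_W, np.zeros(8 * 16))
        assert mu.shape == (1, 50, 8, 16)

    def test_zero_features_zero_capsules(self):
        cfg = LaneConfig(kernel_size=3)
        mu = primary_caps(
            np.zeros((5, 10)), cfg, np.ones((10, 128)), np.zeros(128)
        )
        np.testing.assert_array_equal(mu, 0.0)

    def test_norms_below_one(self, rng):
        cfg = LaneConfig(kernel_size=3)
        feats = rng.normal(0, 10, size=(4, 10))
        mu = primary_caps(feats, cfg, rng.normal(size=(10, 128)), np.zeros(128))
        norms = np.linalg.norm(mu.reshape(4, 8, 16), axis=-1)
        assert np.all(norms < 1.0)

    def test_stride_subsamples_positions(self, rng):
        cfg = LaneConfig(kernel_size=3, primary_stride=9)
        feats = rng.random((1000, 10))
        mu = primary_caps(feats, cfg, rng.normal(size=(10, 128)), np.zeros(128))
        assert mu.shape[0] == 112  # ceil(1000 / 9)


class TestDynamicRouting:
    def test_single_pair_degenerate(self, rng):
        u_hat = rng.normal(size=(1, 1, 4))
        v, c = dynamic_routing(u_hat, iterations=3)
        np.testing.assert_allclose(c, 1.0)
        np.testing.assert_allclose(v[0], squash(u_hat[0, 0]), rtol=1e-10)

    def test_one_iteration_uniform_couplings(self, rng):
        u_hat = rng.normal(size=(4, 5, 3))
        _, c = dynamic_routing(u_hat, iterations=1)
        np.testing.assert_allclose(c, 1.0 / 5.0)

    @pytest.mark.parametrize("variant", ["sabour", "as_printed"])
    def test_matches_straight_line_oracle(self, rng, variant):
        u_hat = rng.normal(size=(3, 2, 4))
        v, c = dynamic_routing(u_hat, iterations=5, squash_variant=variant)
        v_ref, c_ref = routing_oracle(u_hat, iterations=5, variant=variant)
        np.testing.assert_allclose(v, v_ref, rtol=1e-8, atol=1e-12)
        np.testing.assert_allclose(c, c_ref, rtol=1e-8, atol=1e-12)

    def test_coupling_rows_sum_to_one(self, rng):
        u_hat = rng.normal(size=(10, 4, 6))
        for iterations in (1, 2, 5):
            _, c = dynamic_routing(u_hat, iterations=iterations)
            np.testing.assert_allclose(c.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(c >= 0)

    def test_permutation_equivariant_in_input_index(self, rng):
        u_hat = rng.normal(size=(6, 3, 4))
        perm = rng.permutation(6)
        v, c = dynamic_routing(u_hat, iterations=4)
        v_p, c_p = dynamic_routing(u_hat[perm], iterations=4)
        np.testing.assert_allclose(v, v_p, rtol=1e-9)
        np.testing.assert_allclose(c[perm], c_p, rtol=1e-9)

    def test_requires_positive_iterations(self, rng):
        with pytest.raises(ValueError, match="iterations"):
            dynamic_routing(rng.normal(size=(2, 2, 2)), iterations=0)


class TestHiddenCaps:
    def lane(self):
        return LaneConfig(
            kernel_size=3, primary_channels=2, capsule_dim=3,
            hidden_capsules=2, routing_iterations=3,
        )

    def test_zero_primary_zero_hidden(self, rng):
        cfg = self.lane()
        hid_W = rng.normal(size=(2, 2, 3, 3))
        v, _ = hidden_caps(np.zeros((4, 2, 3)), cfg, hid_W)
        np.testing.assert_allclose(v, 0.0, atol=1e-7)

    def test_default_lane_output_shape(self, rng):
        cfg = LaneConfig(kernel_size=3)
        mu = rng.normal(size=(10, 8, 16)) * 0.1
        v, c = hidden_caps(mu, cfg, rng.normal(size=(8, 8, 16, 16)))
        assert v.shape == (8, 16)  # eight 16D hidden capsules
        assert c.shape == (80, 8)

    def test_weight_sharing_position_permutation_invariance(self, rng):
        # identical capsule vectors at every position: permuting positions
        # must leave the routed outputs unchanged because W is shared
        cfg = self.lane()
        hid_W = rng.normal(size=(2, 2, 3, 3))
        base = rng.normal(size=(1, 2, 3))
        mu = np.repeat(base, 5, axis=0)
        perm = rng.permutation(5)
        v1, _ = hidden_caps(mu, cfg, hid_W)
        v2, _ = hidden_caps(mu[perm], cfg, hid_W)
        np.testing.assert_allclose(v1, v2, rtol=1e-10)

    def test_shape_mismatch_raises_configuration_error(self, rng):
        with pytest.raises(ConfigurationError, match="shape"):
            hidden_caps(
                rng.normal(size=(4, 2, 3)), self.lane(),
                rng.normal(size=(2, 2, 3, 4)),
            )


class TestForward:
    def test_probabilities_sum_to_one(self, tiny_net, rng):
        params = init_params(tiny_net, rng)
        x = rng.random((4, 5, 4))
        probs = forward(x, tiny_net, params)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(probs >= 0)

    def test_deterministic_at_inference(self, tiny_net, rng):
        params = init_params(tiny_net, rng)
        x = rng.random((5, 4))
        np.testing.assert_array_equal(
            forward(x, tiny_net, params), forward(x, tiny_net, params)
        )

    def test_matches_composed_oracle(self, tiny_net, rng):
        params = init_params(tiny_net, rng)
        for _ in range(5):
            x = rng.normal(size=(5, 4))
            probs = forward(x, tiny_net, params)
            expected = forward_oracle(x, tiny_net, params)
            np.testing.assert_allclose(probs, expected, rtol=1e-5)


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self, tiny_net, rng):
        params = init_params(tiny_net, rng)
        x = rng.random((2, 5, 4))
        y = np.array([0, 1])
        _, grads, _ = loss_and_grads(x, y, tiny_net, params, train=False)
        eps = 1e-6
        for key, w in params.items():
            flat = w.reshape(-1)
            # spot-check a handful of coordinates per tensor
            for idx in rng.choice(flat.size, size=min(5, flat.size),
                                  replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _, _ = loss_and_grads(x, y, tiny_net, params, train=False)
                flat[idx] = orig - eps
                lm, _, _ = loss_and_grads(x, y, tiny_net, params, train=False)
                flat[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert grads[key].reshape(-1)[idx] == pytest.approx(
                    numeric, rel=1e-4, abs=1e-8
                ), key


class TestNetworkConfig:
    def test_default_has_eight_lanes_with_published_kernels(self):
        cfg = NetworkConfig()
        assert tuple(l.kernel_size for l in cfg.lanes) == (
            1, 3, 5, 9, 15, 21, 27, 33
        )
        assert cfg.input_len == 1000 and cfg.dense_units == 128

    def test_roundtrip_through_dict(self, tiny_net):
        again = NetworkConfig.from_dict(tiny_net.to_dict())
        assert again == tiny_net

    def test_rejects_even_kernel(self):
        with pytest.raises(ValueError, match="odd"):
            LaneConfig(kernel_size=4)
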