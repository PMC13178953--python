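"""Forward-computation tests: mask construction, masked convolution,
anatomy fusion and the end-to-end pass against scripted oracles."""

import numpy as np
import pytest

from maskgnn.graph import BrainGraph
from maskgnn.model import (
    GraphSample,
    LayerParams,
    forward,
    fuse_as,
    load_params,
    mask_from_params,
    maskgnn_layer,
    save_params,
)

from conftest import random_graph_sample, small_params


class TestMask:
    def test_zero_params_give_half(self):
        np.testing.assert_allclose(mask_from_params(np.zeros((3, 3))), 0.5)

    def test_analytic_value(self):
        v = np.zeros((2, 2))
        v[0, 1] = v[1, 0] = 1.0
        m = mask_from_params(v)
        assert m[0, 1] == pytest.approx(1 / (1 + np.exp(-2.0)), abs=1e-6)
        assert m[0, 1] == pytest.approx(0.88080, abs=1e-5)

    def test_exactly_symmetric_and_open_interval(self, rng):
        m = mask_from_params(rng.normal(scale=3, size=(6, 6)))
        np.testing.assert_array_equal(m, m.T)
        assert (m > 0).all() and (m < 1).all()

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            mask_from_params(np.zeros((2, 3)))


class TestMaskGNNLayer:
    def test_zero_input_gives_zero(self, rng):
        sample = random_graph_sample(rng, q=4)
        layer = LayerParams(weight=rng.normal(size=(2, 3)), activation="relu")
        out = maskgnn_layer(np.zeros((4, 2)), sample.graph, np.full((4, 4), 0.5), layer)
        np.testing.assert_array_equal(out, 0.0)

    def test_single_node_analytic(self):
        graph = BrainGraph(adjacency=np.zeros((1, 1)), node_features=np.array([[2.0]]))
        layer = LayerParams(weight=np.array([[3.0]]), activation="identity")
        m = np.array([[0.4]])
        out = maskgnn_layer(np.array([[2.0]]), graph, m, layer)
        # norm_adjacency = [1]; out = (m + 1) * h * theta
        assert out[0, 0] == pytest.approx(1.4 * 2.0 * 3.0)

    def test_path_graph_matches_hand_product(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        h = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 1.0]])
        graph = BrainGraph(adjacency=adj, node_features=h)
        mask = np.full((3, 3), 0.5)
        layer = LayerParams(weight=np.eye(2), activation="identity")
        # explicit operator: (M + I) ⊙ (D̃^{-1/2} Ã D̃^{-1/2})
        a_tilde = adj + np.eye(3)
        d = np.diag(1 / np.sqrt(a_tilde.sum(1)))
        p = (mask + np.eye(3)) * (d @ a_tilde @ d)
        np.testing.assert_allclose(maskgnn_layer(h, graph, mask, layer), p @ h)


class TestFuseAS:
    def test_empty_block_is_identity(self, rng):
        h = rng.normal(size=(4, 3))
        np.testing.assert_array_equal(fuse_as(h, np.zeros((4, 0))), h)

    def test_widths_add(self, rng):
        out = fuse_as(rng.normal(size=(5, 8)), rng.uniform(size=(5, 11)))
        assert out.shape == (5, 19)

    def test_rowwise_concatenation(self, rng):
        h = rng.normal(size=(4, 2))
        c = rng.uniform(size=(4, 3))
        out = fuse_as(h, c)
        np.testing.assert_array_equal(out[2], np.concatenate([h[2], c[2]]))

    def test_row_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            fuse_as(rng.normal(size=(4, 2)), rng.uniform(size=(3, 3)))


def scripted_forward(sample, params):
    """Straight-line re-implementation of the forward formulas."""
    m = 1 / (1 + np.exp(-(params.mask.v_params + params.mask.v_params.T)))
    s = sample.graph.norm_adjacency
    p = (m + np.eye(m.shape[0])) * s
    z1 = p @ sample.graph.node_features @ params.layer1.weight + params.layer1.bias
    a1 = np.maximum(z1, 0)
    h1 = np.hstack([a1, sample.as_features])
    h2 = p @ h1 @ params.layer2.weight + params.layer2.bias
    pooled = h2.mean(axis=0)
    return pooled @ params.readout_weight + params.readout_bias


class TestForward:
    def test_zero_inputs_zero_prediction(self, rng):
        sample = random_graph_sample(rng, q=3)
        sample.graph.node_features[:] = 0.0
        sample.as_features[:] = 0.0
        params = small_params(rng, q=3)
        pred, _ = forward(sample, params)
        np.testing.assert_allclose(pred, 0.0, atol=1e-15)

    def test_matches_scripted_oracle(self, rng):
        sample = random_graph_sample(rng, q=3, d_c=2)
        params = small_params(rng, q=3, d_c=2)
        params.mask.v_params[:] = rng.normal(size=(3, 3))
        pred, cache = forward(sample, params)
        np.testing.assert_allclose(pred, scripted_forward(sample, params), atol=1e-12)
        assert cache["embeddings"].shape == (3, 3)

    def test_permutation_consistency(self, rng):
        q = 6
        sample = random_graph_sample(rng, q=q, d_c=4)
        params = small_params(rng, q=q, d_c=4)
        params.mask.v_params[:] = rng.normal(size=(q, q))
        pred, _ = forward(sample, params)

        perm = rng.permutation(q)
        pg = BrainGraph(
            adjacency=sample.graph.adjacency[np.ix_(perm, perm)],
            node_features=sample.graph.node_features[perm],
        )
        psample = GraphSample(
            graph=pg, as_features=sample.as_features[perm], label=sample.label
        )
        pparams = params.copy()
        pparams.mask.v_params = params.mask.v_params[np.ix_(perm, perm)]
        ppred, _ = forward(psample, pparams)
        np.testing.assert_allclose(ppred, pred, atol=1e-10)

    def test_mask_is_shared_object(self, rng):
        params = small_params(rng, q=4)
        sample = random_graph_sample(rng, q=4)
        before, _ = forward(sample, params)
        params.mask.v_params += 1.0  # mutate the single shared EdgeMask
        after, _ = forward(sample, params)
        assert not np.allclose(before, after)

    def test_zero_mask_limit_is_plain_gcn(self, rng):
        # inject M = 0 directly (bypassing the logistic): the identity
        # term alone must reproduce plain normalized propagation
        sample = random_graph_sample(rng, q=4)
        layer = LayerParams(weight=rng.normal(size=(4, 3)), activation="identity")
        h = sample.graph.node_features
        out = maskgnn_layer(h, sample.graph, np.zeros((4, 4)), layer)
        plain = (np.eye(4) * sample.graph.norm_adjacency) @ h @ layer.weight
        np.testing.assert_allclose(out, plain, atol=1e-12)

    def test_eval_forward_is_deterministic(self, rng):
        sample = random_graph_sample(rng, q=4)
        params = small_params(rng, q=4)
        params.dropout = 0.5  # ignored without a dropout mask
        a, _ = forward(sample, params)
        b, _ = forward(sample, params)
        np.testing.assert_array_equal(a, b)


class TestCheckpoint:
    def test_round_trip(self, rng, tmp_path):
        params = small_params(rng, q=4, d_c=2, n_out=2)
        params.mask.v_params[:] = rng.normal(size=(4, 4))
        path = tmp_path / "ckpt.npz"
        save_params(params, path)
        loaded = load_params(path)
        np.testing.assert_array_equal(loaded.mask.v_params, params.mask.v_params)
        np.testing.assert_array_equal(loaded.layer2.weight, params.layer2.weight)
        assert loaded.layer1.activation == "relu"
        assert loaded.n_outputs == 2


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    @given(
        arrays(
            float,
            st.tuples(st.integers(2, 8), st.integers(2, 8)).filter(lambda s: s[0] == s[1]),
            elements=st.floats(-15, 15, allow_nan=False, width=64),
        )
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_mask_symmetry_property(v):
        """For free parameters below the float64 saturation point of the
        logistic, the derived mask is exactly symmetric with entries
        strictly inside (0, 1)."""
        m = mask_from_params(v)
        np.testing.assert_array_equal(m, m.T)
        assert (m > 0).all() and (m < 1).all()

except ImportError:  # pragma: no cover - hypothesis is an optional test extra
    pass
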