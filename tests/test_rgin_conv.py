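"""Cluster-conditioned weights and the RGIN message-passing update."""

import numpy as np
import pytest

from brainrgin import autodiff as ad
from brainrgin.rgin_conv import (
    MLPParams,
    RGINLayerParams,
    cluster_weights,
    init_rgin_params,
    rgin_forward,
)
from oracles import cluster_weights_direct, dense_rgin_oracle


def make_params(theta1, theta2, bias=None, eps=0.0, aggregation="sum"):
    theta2 = np.asarray(theta2, dtype=float)
    if bias is None:
        bias = np.zeros(theta2.shape[1:])
    return RGINLayerParams(
        theta1=ad.Tensor(np.asarray(theta1, dtype=float)),
        theta2=ad.Tensor(theta2),
        bias=ad.Tensor(np.asarray(bias, dtype=float)),
        epsilon=ad.Tensor(float(eps)),
        mlp=None,
        aggregation=aggregation,
    )


def onehot(i, n):
    r = np.zeros(n)
    r[i] = 1.0
    return r


class TestClusterWeights:
    def test_single_cluster_collapses_to_basis_plus_bias(self, rng):
        beta = rng.normal(size=(1, 3, 2))
        b = rng.normal(size=(3, 2))
        params = make_params(np.ones((1, 4)), beta, b)
        w = cluster_weights(onehot(2, 4), params)
        np.testing.assert_allclose(w.data, beta[0] + b, atol=1e-12)

    def test_negative_scores_rectify_to_bias_only(self, rng):
        params = make_params(-np.ones((3, 5)), rng.normal(size=(3, 2, 2)),
                             rng.normal(size=(2, 2)))
        w = cluster_weights(onehot(1, 5), params)
        np.testing.assert_allclose(w.data, params.bias.data, atol=1e-12)

    def test_basis_form_equals_direct_form_on_random_instances(self, rng):
        """Both printed forms of the node weight map agree (100 draws)."""
        for _ in range(100):
            theta1 = rng.normal(size=(7, 53))
            theta2 = rng.normal(size=(7, 4, 3))
            bias = rng.normal(size=(4, 3))
            roi = int(rng.integers(53))
            params = make_params(theta1, theta2, bias)
            expected = cluster_weights_direct(theta1, theta2, bias, roi)
            got = cluster_weights(onehot(roi, 53), params)
            np.testing.assert_allclose(got.data, expected, atol=1e-6)

    def test_rejects_non_onehot_encoding(self, rng):
        params = make_params(rng.normal(size=(2, 4)), rng.normal(size=(2, 2, 2)))
        with pytest.raises(ValueError):
            cluster_weights(np.array([0.5, 0.5, 0.0, 0.0]), params)


class TestRGINForward:
    def test_isolated_node_keeps_only_self_term(self, rng):
        params = make_params(rng.normal(size=(2, 1)), rng.normal(size=(2, 3, 3)))
        h = rng.normal(size=(1, 3))
        out = rgin_forward(np.zeros((1, 1)), np.array([0]), h, params)
        w = cluster_weights(onehot(0, 1), params)
        np.testing.assert_allclose(out.data[0], w.data @ h[0], atol=1e-10)

    def test_two_node_hand_example(self):
        """Unit edge, identity basis, zero bias and eps: each node ends
        up with the sum of both embeddings."""
        params = make_params(np.ones((1, 2)), np.eye(3)[None])
        adj = np.array([[0.0, 1.0], [1.0, 0.0]])
        h = np.array([[1.0, 2.0, 3.0], [10.0, 20.0, 30.0]])
        out = rgin_forward(adj, np.array([0, 1]), h, params)
        np.testing.assert_allclose(out.data, [h[0] + h[1], h[0] + h[1]], atol=1e-12)

    @pytest.mark.parametrize("aggregation", ["sum", "mean"])
    def test_matches_dense_oracle_on_random_graphs(self, rng, aggregation):
        for _ in range(40):
            n = int(rng.integers(2, 7))
            adj = rng.normal(size=(n, n)) * (rng.random((n, n)) < 0.6)
            adj = np.triu(adj, 1)
            adj = adj + adj.T
            roi = rng.permutation(8)[:n]
            h = rng.normal(size=(n, 3))
            theta1 = rng.normal(size=(3, 8))
            theta2 = rng.normal(size=(3, 2, 3))
            bias = rng.normal(size=(2, 3))
            eps = float(rng.normal())
            params = make_params(theta1, theta2, bias, eps, aggregation)
            expected = dense_rgin_oracle(adj, roi, h, theta1, theta2, bias,
                                         eps, aggregation)
            got = rgin_forward(adj, roi, h, params)
            np.testing.assert_allclose(got.data, expected, atol=1e-6)

    def test_reduces_to_gin_update(self, rng):
        """K=1, unit assignment, identity basis, zero bias, unit edges and
        sum aggregation reproduce the plain injective GIN update."""
        n, d = 5, 3
        adj = (np.ones((n, n)) - np.eye(n))
        h = rng.normal(size=(n, d))
        eps = 0.37
        params = make_params(np.ones((1, n)), np.eye(d)[None], eps=eps)
        got = rgin_forward(adj, np.arange(n), h, params)
        gin = (1 + eps) * h + (h.sum(axis=0, keepdims=True) - h)
        np.testing.assert_allclose(got.data, gin, atol=1e-6)

    def test_permutation_equivariance(self, rng):
        n = 6
        adj = rng.normal(size=(n, n))
        adj = np.triu(adj, 1) + np.triu(adj, 1).T
        roi = np.arange(n)
        h = rng.normal(size=(n, 4))
        params = make_params(rng.normal(size=(3, n)), rng.normal(size=(3, 4, 4)),
                             rng.normal(size=(4, 4)), eps=0.2)
        base = rgin_forward(adj, roi, h, params).data
        perm = rng.permutation(n)
        permuted = rgin_forward(adj[np.ix_(perm, perm)], roi[perm], h[perm],
                                params).data
        np.testing.assert_allclose(permuted, base[perm], atol=1e-6)

    def test_messages_linear_in_edge_weight(self, rng):
        """With an identity MLP, doubling one edge weight exactly doubles
        that neighbour's contribution."""
        n = 4
        adj = np.zeros((n, n))
        adj[0, 1] = adj[1, 0] = 0.5
        adj[0, 2] = adj[2, 0] = -0.3
        h = rng.normal(size=(n, 3))
        params = make_params(rng.normal(size=(2, n)), rng.normal(size=(2, 3, 3)))
        base = rgin_forward(adj, np.arange(n), h, params).data
        adj2 = adj.copy()
        adj2[0, 1] = adj2[1, 0] = 1.0
        doubled = rgin_forward(adj2, np.arange(n), h, params).data
        w1 = cluster_weights(onehot(1, n), params).data
        contrib = w1 @ (0.5 * h[1])
        np.testing.assert_allclose(doubled[0] - base[0], contrib, atol=1e-10)

    def test_rejects_nonfinite_and_bad_aggregation(self, rng):
        params = make_params(np.ones((1, 2)), np.eye(2)[None])
        with pytest.raises(ValueError):
            rgin_forward(np.array([[0.0, np.inf], [np.inf, 0.0]]),
                         np.array([0, 1]), rng.normal(size=(2, 2)), params)
        with pytest.raises(ValueError):
            make_params(np.ones((1, 2)), np.eye(2)[None], aggregation="median")

    def test_mlp_update_applies_two_affine_maps(self, rng):
        d = 3
        mlp = MLPParams(
            w1=ad.Tensor(rng.normal(size=(d, d))),
            b1=ad.Tensor(rng.normal(size=d)),
            w2=ad.Tensor(rng.normal(size=(d, d))),
            b2=ad.Tensor(rng.normal(size=d)),
        )
        params = RGINLayerParams(
            theta1=ad.Tensor(np.ones((1, 1))),
            theta2=ad.Tensor(np.eye(d)[None]),
            bias=ad.Tensor(np.zeros((d, d))),
            epsilon=ad.Tensor(0.0),
            mlp=mlp,
            aggregation="sum",
        )
        h = rng.normal(size=(1, d))
        out = rgin_forward(np.zeros((1, 1)), np.array([0]), h, params)
        pre = h[0]
        expected = mlp.w2.data @ np.maximum(mlp.w1.data @ pre + mlp.b1.data, 0) \
            + mlp.b2.data
        np.testing.assert_allclose(out.data[0], expected, atol=1e-10)

    def test_gradients_reach_all_layer_parameters(self, rng):
        params = init_rgin_params(rng, 2, 4, 3, 3)
        adj = np.abs(rng.normal(size=(4, 4)))
        np.fill_diagonal(adj, 0.0)
        out = rgin_forward(adj, np.arange(4), rng.normal(size=(4, 3)), params)
        ad.tsum(out * out).backward()
        for name, p in params.parameters("l").items():
            assert p.grad is not None and np.any(p.grad != 0), name
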