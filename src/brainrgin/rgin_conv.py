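"""ROI-aware graph-isomorphism (RGIN) convolution.

The layer merges two ideas:

* a GIN-style injective node update — ``h_i' = MLP((1 + eps) * m_self +
  aggregated neighbour messages)`` with a trainable ``eps`` weighting the
  node against its neighbourhood, and
* cluster-conditioned weights in the style of relational GCNs — every
  node's linear map ``W_i`` is a non-negative combination of ``K`` shared
  basis matrices, with combination scores conditioned on the node's
  original ROI identity (a one-hot position encoding):

  ``W_i = sum_u relu(theta1 @ r_i)_u * beta_u + b``.

Because the assignment scores depend only on the ROI index, ROIs that the
model learns to place in the same functional cluster share an update
rule, while the basis decomposition keeps the parameter count at
``K * d_out * d_in`` instead of ``N * d_out * d_in``.

Messages are multiplied by the signed correlation edge weight ``e_ij``,
so strongly (anti-)correlated neighbours contribute proportionally.
The ``(1 + eps)`` factor scales only the self term; neighbour messages
are aggregated by sum (default) or mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "MLPParams",
    "RGINLayerParams",
    "init_rgin_params",
    "cluster_weights",
    "rgin_forward",
]

_AGGREGATIONS = ("sum", "mean")


@dataclass
class MLPParams:
    """Two affine maps with a ReLU between (the '2-layered MLP' update)."""

    w1: Tensor  # (hidden, d_in)
    b1: Tensor  # (hidden,)
    w2: Tensor  # (d_out, hidden)
    b2: Tensor  # (d_out,)

    def __call__(self, x: Tensor) -> Tensor:
        h = ad.relu(ad.matmul(x, ad.swapaxes(self.w1, 0, 1)) + self.b1)
        return ad.matmul(h, ad.swapaxes(self.w2, 0, 1)) + self.b2

    def parameters(self, prefix: str) -> dict[str, Tensor]:
        return {
            f"{prefix}.w1": self.w1,
            f"{prefix}.b1": self.b1,
            f"{prefix}.w2": self.w2,
            f"{prefix}.b2": self.b2,
        }


@dataclass
class RGINLayerParams:
    """Parameters of one RGIN layer.

    ``theta1`` is ``(K, N0)``: column ``i`` holds the pre-rectifier
    cluster-assignment scores of original ROI ``i``.  ``theta2`` stacks
    the ``K`` basis matrices as ``(K, d_out, d_in)``.  ``mlp`` may be
    ``None``, in which case the update MLP is the identity (useful for
    closed-form checks).
    """

    theta1: Tensor
    theta2: Tensor
    bias: Tensor  # (d_out, d_in)
    epsilon: Tensor  # scalar
    mlp: MLPParams | None
    aggregation: str = "sum"

    def __post_init__(self):
        if self.aggregation not in _AGGREGATIONS:
            raise ValueError(f"aggregation must be one of {_AGGREGATIONS}")
        k, _ = self.theta1.shape
        k2, d_out, d_in = self.theta2.shape
        if k != k2:
            raise ValueError("theta1 and theta2 disagree on the cluster count K")
        if self.bias.shape != (d_out, d_in):
            raise ValueError("bias shape must match the basis matrices")

    @property
    def n_clusters(self) -> int:
        return self.theta2.shape[0]

    @property
    def d_out(self) -> int:
        return self.theta2.shape[1]

    @property
    def d_in(self) -> int:
        return self.theta2.shape[2]

    def parameters(self, prefix: str) -> dict[str, Tensor]:
        out = {
            f"{prefix}.theta1": self.theta1,
            f"{prefix}.theta2": self.theta2,
            f"{prefix}.bias": self.bias,
            f"{prefix}.epsilon": self.epsilon,
        }
        if self.mlp is not None:
            out.update(self.mlp.parameters(f"{prefix}.mlp"))
        return out


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[-1], shape[-2] if len(shape) > 1 else shape[-1]
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, scale, size=shape)


def init_rgin_params(
    rng: np.random.Generator,
    n_clusters: int,
    n_rois: int,
    d_in: int,
    d_out: int,
    aggregation: str = "sum",
    identity_mlp: bool = False,
) -> RGINLayerParams:
    """Seeded initialisation: Glorot basis matrices, standard-normal
    cluster scores (about half rectified to zero at start), eps = 0."""
    mlp = None
    if not identity_mlp:
        mlp = MLPParams(
            w1=ad.parameter(_glorot(rng, (d_out, d_out))),
            b1=ad.parameter(np.zeros(d_out)),
            w2=ad.parameter(_glorot(rng, (d_out, d_out))),
            b2=ad.parameter(np.zeros(d_out)),
        )
    return RGINLayerParams(
        theta1=ad.parameter(rng.normal(0.0, 1.0, size=(n_clusters, n_rois))),
        theta2=ad.parameter(_glorot(rng, (n_clusters, d_out, d_in))),
        bias=ad.parameter(np.zeros((d_out, d_in))),
        epsilon=ad.parameter(0.0),
        mlp=mlp,
        aggregation=aggregation,
    )


def cluster_weights(r_onehot: np.ndarray, params: RGINLayerParams) -> Tensor:
    """Node-specific weight matrix from a one-hot position encoding.

    Evaluates ``W_i = sum_u alpha_iu beta_u + b`` with
    ``alpha_i = relu(theta1 @ r_i)`` — the basis-combination form, which
    is algebraically identical to applying the stacked bases directly to
    the rectified assignment scores.
    """
    r = np.asarray(r_onehot, dtype=np.float64)
    if r.shape != (params.theta1.shape[1],):
        raise ValueError(
            f"one-hot encoding has length {r.shape}, expected {params.theta1.shape[1]}"
        )
    if not (np.count_nonzero(r) == 1 and np.isclose(r.sum(), 1.0)):
        raise ValueError("position encoding must be one-hot")
    alpha = ad.relu(ad.einsum("kn,n->k", params.theta1, r))
    return ad.einsum("k,koi->oi", alpha, params.theta2) + params.bias


def _as_batched(
    adjacency: np.ndarray, roi_index: np.ndarray, h
) -> tuple[np.ndarray, np.ndarray, Tensor, bool]:
    h = ad.astensor(h)
    adjacency = np.asarray(adjacency, dtype=np.float64)
    roi_index = np.asarray(roi_index, dtype=np.int64)
    if h.ndim == 2:
        return adjacency[None], roi_index[None], ad.reshape(h, (1, *h.shape)), True
    return adjacency, roi_index, h, False


def rgin_forward(
    adjacency: np.ndarray,
    roi_index: np.ndarray,
    h,
    params: RGINLayerParams,
) -> Tensor:
    """One RGIN convolution over a batch of graphs.

    Parameters
    ----------
    adjacency:
        ``(B, N, N)`` (or unbatched ``(N, N)``) signed weighted adjacency
        with zero diagonal; entry ``(i, j)`` is the edge weight ``e_ij``
        or 0 for absent edges.  Treated as a constant of the tape.
    roi_index:
        ``(B, N)`` integer original-ROI identity of every current node;
        indexes the columns of ``theta1`` (the one-hot encodings survive
        pooling as plain indices).
    h:
        ``(B, N, d_in)`` node embeddings (rows of the FNC matrix at the
        first layer).

    Returns the updated ``(B, N, d_out)`` embeddings
    ``MLP((1 + eps) W_i h_i + AGG_j e_ij W_j h_j)``; isolated nodes
    receive only the self term.
    """
    adjacency, roi_index, h, squeeze = _as_batched(adjacency, roi_index, h)
    if not np.all(np.isfinite(adjacency)):
        raise ValueError("adjacency contains non-finite entries")
    if not np.all(np.isfinite(h.data)):
        raise ValueError("node embeddings contain non-finite entries")
    b_sz, n_nodes, d_in = h.shape
    if adjacency.shape != (b_sz, n_nodes, n_nodes):
        raise ValueError("adjacency shape does not match the embedding matrix")
    if roi_index.shape != (b_sz, n_nodes):
        raise ValueError("roi_index shape does not match the embedding matrix")
    if d_in != params.d_in:
        raise ValueError(f"layer expects d_in={params.d_in}, got {d_in}")

    # alpha[u, i] for every original ROI, gathered per current node
    alpha_all = ad.relu(ad.swapaxes(params.theta1, 0, 1))  # (N0, K)
    alpha_g = ad.take(alpha_all, roi_index)  # (B, N, K)

    # V[b, n] = W_{roi(b,n)} h[b, n] = sum_u alpha_u (h beta_u^T) + h b^T,
    # arranged as dense matmuls so the contraction stays in BLAS
    n_k, d_out = params.n_clusters, params.d_out
    basis_flat = ad.reshape(params.theta2, (n_k * d_out, d_in))
    h_bases = ad.matmul(h, ad.swapaxes(basis_flat, 0, 1))  # (B, N, K*d_out)
    h_bases = ad.reshape(h_bases, (b_sz, n_nodes, n_k, d_out))
    v = ad.tsum(h_bases * ad.reshape(alpha_g, (b_sz, n_nodes, n_k, 1)), axis=2)
    v = v + ad.matmul(h, ad.swapaxes(params.bias, 0, 1))

    msg = ad.matmul(Tensor(adjacency), v)
    if params.aggregation == "mean":
        deg = np.maximum((adjacency != 0).sum(axis=-1, keepdims=True), 1)
        msg = msg * (1.0 / deg)

    m = (1.0 + params.epsilon) * v + msg
    out = m if params.mlp is None else params.mlp(m)
    if squeeze:
        out = ad.reshape(out, out.shape[1:])
    return out
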