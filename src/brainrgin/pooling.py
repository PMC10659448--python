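"""ROI-aware TopK pooling.

Nodes are scored by projecting their embeddings onto a learnable vector
``omega`` (normalised by ``||omega||_2``), the scores are standardised
per graph, and the ``k = ceil(ratio * N)`` highest-scoring nodes
survive.  Surviving features are gated elementwise by the sigmoid of the
standardised score — so the selection itself stays differentiable
through the gate — and the adjacency is restricted to edges whose both
endpoints survive, with weights unchanged.  Original ROI indices ride
along so that deeper layers and the interpretation stage always know
which brain region a surviving node is.

Numerical conventions: the standard deviation in the score
normalisation is the population one with a 1e-8 guard added to the
denominator (a constant score vector standardises to all zeros), and
score ties are broken toward the lower node index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["PoolingParams", "PooledGraph", "score_nodes", "topk_pool", "STD_GUARD"]

STD_GUARD = 1e-8


@dataclass
class PoolingParams:
    """Learnable projection vector and the survival ratio."""

    omega: Tensor
    ratio: float

    def __post_init__(self):
        if not (0.0 < self.ratio <= 1.0):
            raise ValueError("pooling ratio must lie in (0, 1]")

    def parameters(self, prefix: str) -> dict[str, Tensor]:
        return {f"{prefix}.omega": self.omega}


@dataclass
class PooledGraph:
    """The graph surviving one TopK layer.

    ``selected`` holds row positions into the pre-pooling node order
    (per graph, in descending score order); ``roi_index`` holds the
    survivors' original ROI identities.  ``scores_raw``/``scores_norm``
    are the pre-pooling projection scores of *all* nodes, kept for the
    TPK loss and interpretation.
    """

    h: Tensor  # (B, k, d) gated surviving features
    selected: np.ndarray  # (B, k) int
    scores_raw: Tensor  # (B, N)
    scores_norm: Tensor  # (B, N)
    adjacency: np.ndarray  # (B, k, k)
    roi_index: np.ndarray  # (B, k) int
    k: int


def init_pooling_params(rng: np.random.Generator, d: int, ratio: float) -> PoolingParams:
    omega = rng.normal(0.0, 1.0, size=d)
    omega /= np.linalg.norm(omega)
    return PoolingParams(omega=ad.parameter(omega), ratio=ratio)


def score_nodes(h, omega) -> tuple[Tensor, Tensor]:
    """Projection scores ``s = H omega / ||omega||`` and their per-graph
    standardisation ``(s - mean) / (std + guard)``.

    Accepts ``(B, N, d)`` or a single ``(N, d)`` matrix.
    """
    h = ad.astensor(h)
    omega = ad.astensor(omega)
    if np.linalg.norm(omega.data) == 0.0:
        raise ValueError("projection vector omega must be nonzero")
    squeeze = h.ndim == 2
    if squeeze:
        h = ad.reshape(h, (1, *h.shape))
    if omega.shape != (h.shape[-1],):
        raise ValueError("omega length must match the feature width")
    norm = ad.sqrt(ad.tsum(omega * omega))
    proj = ad.matmul(h, ad.reshape(omega, (omega.shape[0], 1)))
    s = ad.reshape(proj, h.shape[:2]) / norm
    mu = ad.tmean(s, axis=-1, keepdims=True)
    centred = s - mu
    std = ad.sqrt(ad.tmean(centred * centred, axis=-1, keepdims=True))
    s_norm = centred / (std + STD_GUARD)
    if squeeze:
        s = ad.reshape(s, s.shape[1:])
        s_norm = ad.reshape(s_norm, s_norm.shape[1:])
    return s, s_norm


def topk_indices(scores_norm: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest scores per row, descending, ties toward
    the lower index (stable argsort of the negated scores)."""
    order = np.argsort(-scores_norm, axis=-1, kind="stable")
    return order[..., :k]


def topk_pool(
    adjacency: np.ndarray,
    roi_index: np.ndarray,
    h,
    params: PoolingParams,
) -> PooledGraph:
    """Select, gate and subset one batch of graphs.

    ``k = ceil(ratio * N)`` (never zero).  Gated features are
    ``(H * sigmoid(s_norm))`` restricted to the selected rows; the
    adjacency keeps exactly the edges between selected nodes.
    """
    h = ad.astensor(h)
    squeeze = h.ndim == 2
    if squeeze:
        h = ad.reshape(h, (1, *h.shape))
        adjacency = np.asarray(adjacency)[None]
        roi_index = np.asarray(roi_index)[None]
    adjacency = np.asarray(adjacency, dtype=np.float64)
    roi_index = np.asarray(roi_index, dtype=np.int64)
    b_sz, n_nodes, _ = h.shape
    k = max(1, math.ceil(params.ratio * n_nodes))

    s, s_norm = score_nodes(h, params.omega)
    sel = topk_indices(s_norm.data, k)  # (B, k)

    gated = h * ad.reshape(ad.sigmoid(s_norm), (b_sz, n_nodes, 1))
    h_next = ad.take_along(gated, sel[:, :, None].repeat(h.shape[-1], axis=2), axis=1)

    batch_ix = np.arange(b_sz)[:, None, None]
    adj_next = adjacency[batch_ix, sel[:, :, None], sel[:, None, :]]
    roi_next = np.take_along_axis(roi_index, sel, axis=1)

    if squeeze:
        h_next = ad.reshape(h_next, h_next.shape[1:])
        adj_next = adj_next[0]
        roi_next = roi_next[0]
        sel = sel[0]
        s = ad.reshape(s, s.shape[1:])
        s_norm = ad.reshape(s_norm, s_norm.shape[1:])
    return PooledGraph(
        h=h_next,
        selected=sel,
        scores_raw=s,
        scores_norm=s_norm,
        adjacency=adj_next,
        roi_index=roi_next,
        k=k,
    )
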