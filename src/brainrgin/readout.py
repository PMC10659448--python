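"""Graph-level readouts: GARO, SERO, and elementwise mean+max.

A readout collapses a (pooled) node-feature matrix to one fixed-length
vector per graph.  The two attention readouts learn per-node scaling
coefficients in (0, 1):

* GARO (graph-attention readout) — Transformer-style key-query
  attention where the query is computed from the mean-pooled graph
  vector: ``K = W_key H``, ``q = W_query H phi_mean``,
  ``z = sigmoid(q^T K / sqrt(D))``, ``h_G = H z``.
* SERO (squeeze-excitation readout) — squeeze the node features to the
  global average, excite through a two-layer bottleneck, and scale the
  *node* dimension: ``z = sigmoid(W2 relu(W1 (H phi_mean)))``,
  ``h_G = H z``.  ``W2`` has one row per node, so SERO requires a fixed
  node count (deterministic here: ratio-based pooling on a fixed ROI
  count) and is deliberately not permutation-invariant.
* mean+max — concatenated elementwise mean and max over nodes
  (length ``2D``), the non-learnable baseline.

Features are stored nodes-by-channels ``(B, N, D)`` throughout the
package; the formulas above are written in the transposed ``D x N``
orientation, and the implementations below contract the node axis
accordingly.  This is the only place the orientation matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "GAROParams",
    "SEROParams",
    "garo",
    "sero",
    "meanmax_readout",
    "concat_blocks",
]


@dataclass
class GAROParams:
    w_key: Tensor  # (D, D)
    w_query: Tensor  # (D, D)

    def parameters(self, prefix: str) -> dict[str, Tensor]:
        return {f"{prefix}.w_key": self.w_key, f"{prefix}.w_query": self.w_query}


@dataclass
class SEROParams:
    w1: Tensor  # (D, D)
    w2: Tensor  # (N, D) — one row per node at this block

    def parameters(self, prefix: str) -> dict[str, Tensor]:
        return {f"{prefix}.w1": self.w1, f"{prefix}.w2": self.w2}


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    scale = np.sqrt(2.0 / sum(shape))
    return rng.normal(0.0, scale, size=shape)


def init_garo_params(rng: np.random.Generator, d: int) -> GAROParams:
    return GAROParams(
        w_key=ad.parameter(_glorot(rng, (d, d))),
        w_query=ad.parameter(_glorot(rng, (d, d))),
    )


def init_sero_params(rng: np.random.Generator, d: int, n_nodes: int) -> SEROParams:
    return SEROParams(
        w1=ad.parameter(_glorot(rng, (d, d))),
        w2=ad.parameter(_glorot(rng, (n_nodes, d))),
    )


def _batched(h) -> tuple[Tensor, bool]:
    h = ad.astensor(h)
    if h.ndim == 2:
        return ad.reshape(h, (1, *h.shape)), True
    if h.ndim != 3:
        raise ValueError("node features must be (N, D) or (B, N, D)")
    return h, False


def garo(h, params: GAROParams) -> Tensor:
    """Key-query attention readout; returns ``(B, D)`` (or ``(D,)``)."""
    h, squeeze = _batched(h)
    d = h.shape[-1]
    if params.w_key.shape != (d, d) or params.w_query.shape != (d, d):
        raise ValueError("GARO weight matrices must be (D, D) for feature width D")
    b, n, _ = h.shape
    keys = ad.matmul(h, ad.swapaxes(params.w_key, 0, 1))  # (B, N, D)
    h_mean = ad.tmean(h, axis=-2)  # phi_mean over nodes
    q = ad.matmul(h_mean, ad.swapaxes(params.w_query, 0, 1))  # (B, D)
    logits = ad.reshape(ad.matmul(keys, ad.reshape(q, (b, d, 1))), (b, n))
    z = ad.sigmoid(logits / np.sqrt(d))
    out = ad.reshape(ad.matmul(ad.reshape(z, (b, 1, n)), h), (b, d))
    return ad.reshape(out, (d,)) if squeeze else out


def sero(h, params: SEROParams) -> Tensor:
    """Squeeze-excitation readout over the node dimension."""
    h, squeeze = _batched(h)
    _, n, d = h.shape
    if params.w1.shape != (d, d):
        raise ValueError("SERO W1 must be (D, D) for feature width D")
    if params.w2.shape[0] != n or params.w2.shape[1] != d:
        raise ValueError(
            f"SERO W2 is fixed to {params.w2.shape[0]} nodes but got {n}"
        )
    b = h.shape[0]
    z = ad.tmean(h, axis=-2)  # (B, D) squeeze
    hidden = ad.relu(ad.matmul(z, ad.swapaxes(params.w1, 0, 1)))
    z_space = ad.sigmoid(ad.matmul(hidden, ad.swapaxes(params.w2, 0, 1)))  # (B, N)
    out = ad.reshape(ad.matmul(ad.reshape(z_space, (b, 1, n)), h), (b, d))
    return ad.reshape(out, (d,)) if squeeze else out


def meanmax_readout(h) -> Tensor:
    """Concatenated elementwise mean and max over nodes (length 2D)."""
    h, squeeze = _batched(h)
    out = ad.concatenate([ad.tmean(h, axis=-2), ad.amax(h, axis=-2)], axis=-1)
    return ad.reshape(out, (out.shape[-1],)) if squeeze else out


def concat_blocks(summaries: list) -> Tensor:
    """Concatenate per-block graph embeddings in block order."""
    if not summaries:
        raise ValueError("need at least one block summary")
    ts = [ad.astensor(s) for s in summaries]
    ndims = {t.ndim for t in ts}
    if len(ndims) != 1:
        raise ValueError("block summaries disagree on batching")
    return ad.concatenate(ts, axis=-1)
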