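"""Functional-connectivity graph construction.

Turns per-subject ROI time series (rows = regions, columns = time points)
into a Pearson functional network connectivity (FNC) matrix, and the FNC
matrix into an undirected, signed-weighted graph:

* node ``i`` carries the full correlation row of ROI ``i`` as its feature
  vector (unthresholded, self-correlation kept at 1),
* edges are the top fraction of ROI pairs ranked by absolute correlation,
  retaining the *signed* correlation as the edge weight,
* the adjacency matrix has a zero diagonal (no self-loops).

Thresholding ranks by magnitude ("strongest correlations") but keeps
signs because the convolution downstream multiplies messages by the raw
edge weight; anticorrelated regions should push, not pull.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ROITimeSeries",
    "FNCMatrix",
    "FNCGraph",
    "compute_fnc",
    "threshold_edges",
    "build_graph",
]


def _default_labels(n: int) -> list[str]:
    return [f"ROI_{i:02d}" for i in range(n)]


@dataclass
class ROITimeSeries:
    """One subject's ROI-by-time signal matrix.

    ``values`` is ``(n_roi, t)``; at least 2 ROIs and 3 time points are
    required, with no missing values and nonzero variance per row.
    """

    values: np.ndarray
    roi_labels: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-d (n_roi x t) matrix")
        if not self.roi_labels:
            self.roi_labels = _default_labels(self.values.shape[0])

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]

    @property
    def t(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        if self.n_roi < 2:
            raise ValueError("need at least 2 ROIs")
        if self.t < 3:
            raise ValueError(f"need at least 3 time points, got {self.t}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        sd = self.values.std(axis=1)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            names = ", ".join(self.roi_labels[i] for i in dead)
            raise ValueError(f"zero-variance time series for ROI(s): {names}")


@dataclass
class FNCMatrix:
    """Symmetric Pearson correlation matrix between ROI time courses."""

    values: np.ndarray
    roi_labels: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not self.roi_labels:
            self.roi_labels = _default_labels(self.values.shape[0])

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]

    def validate(self, atol: float = 1e-8) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FNC matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("FNC matrix contains non-finite entries")
        if not np.allclose(v, v.T, atol=atol):
            raise ValueError("FNC matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=atol):
            raise ValueError("FNC diagonal must be 1 before graph construction")
        if v.min() < -1 - atol or v.max() > 1 + atol:
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class FNCGraph:
    """Thresholded, signed, undirected graph built from an FNC matrix.

    ``node_features`` row ``i`` is ROI ``i``'s full correlation row;
    ``edges`` lists each retained pair once as ``(i, j)`` with ``i < j``;
    ``adjacency`` is the symmetric weighted matrix with zero diagonal;
    ``roi_index`` maps node position to original ROI position (identity
    here, but propagated through pooling downstream).
    """

    node_features: np.ndarray
    edges: np.ndarray
    edge_weights: np.ndarray
    adjacency: np.ndarray
    roi_index: np.ndarray
    roi_labels: list[str] = field(default_factory=list)
    subject_id: str = ""

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]


def compute_fnc(ts: ROITimeSeries) -> FNCMatrix:
    """Pearson correlation between every pair of ROI time courses.

    Raises if any ROI has zero variance (naming the ROI) or if fewer than
    3 time points are available.
    """
    ts.validate()
    corr = np.corrcoef(ts.values)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return FNCMatrix(corr, list(ts.roi_labels), ts.subject_id)


def threshold_edges(fnc: FNCMatrix, keep_percent: float = 100.0) -> np.ndarray:
    """Top ``keep_percent`` % of ROI pairs by absolute correlation.

    All ``N(N-1)/2`` upper-triangle pairs are ranked by ``|r|`` and the
    top ``ceil(keep_percent/100 * N(N-1)/2)`` retained, so the edge set
    is never empty.  Ties are broken by row-major pair order for
    determinism.  Returns an ``(m, 2)`` integer array with ``i < j``.
    """
    if not (0.0 < keep_percent <= 100.0):
        raise ValueError("keep_percent must lie in (0, 100]")
    fnc.validate()
    n = fnc.n_roi
    iu, ju = np.triu_indices(n, k=1)
    strength = np.abs(fnc.values[iu, ju])
    if not np.all(np.isfinite(strength)):
        raise ValueError("non-finite correlations cannot be thresholded")
    n_pairs = iu.size
    m = math.ceil(keep_percent / 100.0 * n_pairs)
    order = np.argsort(-strength, kind="stable")[:m]
    keep = np.sort(order)  # row-major pair order in the output
    return np.column_stack([iu[keep], ju[keep]])


def build_graph(fnc: FNCMatrix, keep_percent: float = 100.0) -> FNCGraph:
    """Assemble the signed graph: full correlation rows as node features,
    thresholded signed correlations as edges, zero-diagonal adjacency."""
    edges = threshold_edges(fnc, keep_percent)
    n = fnc.n_roi
    weights = fnc.values[edges[:, 0], edges[:, 1]]
    adjacency = np.zeros((n, n), dtype=np.float64)
    adjacency[edges[:, 0], edges[:, 1]] = weights
    adjacency[edges[:, 1], edges[:, 0]] = weights
    return FNCGraph(
        node_features=fnc.values.copy(),
        edges=edges,
        edge_weights=weights,
        adjacency=adjacency,
        roi_index=np.arange(n, dtype=np.int64),
        roi_labels=list(fnc.roi_labels),
        subject_id=fnc.subject_id,
    )
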