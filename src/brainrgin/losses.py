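"""The composite training objective.

Three ingredients, combined as
``L_total = L_smoothL1 + sum_l L_unit^(l) + lambda1 * sum_l L_TPK^(l)``:

* **SmoothL1** regression loss between predicted and target score —
  quadratic ``0.5 (x - y)^2`` inside the unit gap, linear
  ``|x - y| - 0.5`` outside, averaged over the batch.
* **Unit loss** per pooling layer, penalising the projection vector for
  drifting off unit length.  The default is the squared deviation
  ``(||omega||_2 - 1)^2``; the raw deviation ``||omega||_2 - 1`` is
  available as ``unit_norm_mode="raw"`` but is unbounded below (it is
  minimised by shrinking omega to zero), so the squared form is what
  training uses.
* **TPK loss** per pooling layer (binary cross-entropy on the
  descending-sorted sigmoid scores): selected nodes are pushed toward
  score 1 and unselected toward 0, separating survivors from the rest
  and stabilising which ROIs are kept.

All components are non-negative under the defaults, and every function
accepts either plain arrays or tape tensors (returning a tape tensor so
gradients flow in training).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "LossConfig",
    "LossReport",
    "smooth_l1",
    "unit_loss",
    "tpk_loss",
    "total_loss",
]


@dataclass
class LossConfig:
    """Weights and guards of the composite objective."""

    lambda1: float = 0.1  # weight on the TPK terms
    clamp_eps: float = 1e-7  # score clamp before logs
    unit_norm_mode: str = "squared"  # "squared" | "raw"

    def __post_init__(self):
        if self.lambda1 < 0:
            raise ValueError("lambda1 must be non-negative")
        if not (0.0 < self.clamp_eps < 0.5):
            raise ValueError("clamp_eps must lie in (0, 0.5)")
        if self.unit_norm_mode not in ("squared", "raw"):
            raise ValueError("unit_norm_mode must be 'squared' or 'raw'")


@dataclass
class LossReport:
    """Scalar components plus the combined total (a tape tensor)."""

    smooth_l1: float
    unit: list[float]
    tpk: list[float]
    total: Tensor

    def as_dict(self) -> dict[str, float]:
        out = {"smooth_l1": self.smooth_l1, "total": float(self.total.data)}
        for i, u in enumerate(self.unit):
            out[f"unit_{i}"] = u
        for i, t in enumerate(self.tpk):
            out[f"tpk_{i}"] = t
        return out


def smooth_l1(x, y) -> Tensor:
    """Batch-mean SmoothL1: ``0.5 d^2`` for ``|d| < 1`` else ``|d| - 0.5``."""
    x, y = ad.astensor(x), ad.astensor(y)
    if not (np.all(np.isfinite(x.data)) and np.all(np.isfinite(y.data))):
        raise ValueError("smooth_l1 requires finite inputs")
    diff = x - y
    adiff = ad.absolute(diff)
    quad = adiff.data < 1.0  # branch mask, constant on the tape
    per = 0.5 * diff * diff * quad + (adiff - 0.5) * (~quad)
    return ad.tmean(per)


def unit_loss(omega, mode: str = "squared") -> Tensor:
    """Deviation of ``||omega||_2`` from 1 (squared by default)."""
    omega = ad.astensor(omega)
    if omega.size == 0:
        raise ValueError("omega must be nonempty")
    dev = ad.sqrt(ad.tsum(omega * omega)) - 1.0
    if mode == "squared":
        return dev * dev
    if mode == "raw":
        return dev
    raise ValueError("mode must be 'squared' or 'raw'")


def tpk_loss(sorted_scores, k: int, clamp_eps: float = 1e-7) -> Tensor:
    """Binary cross-entropy separating selected from unselected scores.

    ``sorted_scores`` is ``(M, N)`` (or a single length-N vector) of
    sigmoid scores sorted descending per instance — sortedness is the
    caller's contract and is checked.  The first ``k`` entries per
    instance are pushed toward 1, the remaining ``N - k`` toward 0:

    ``-(1/M) sum_m (1/N) [ sum_{i<=k} log s_mi
                           + sum_{i<=N-k} log(1 - s_{m,i+k}) ]``
    """
    s = ad.astensor(sorted_scores)
    if s.ndim == 1:
        s = ad.reshape(s, (1, s.shape[0]))
    if s.ndim != 2:
        raise ValueError("scores must be (M, N)")
    n = s.shape[1]
    if not (0 < k < n):
        raise ValueError(f"k must lie strictly between 0 and N={n}")
    if np.any(np.diff(s.data, axis=1) > 1e-12):
        raise ValueError("scores must be sorted in descending order per instance")
    sc = ad.clip(s, clamp_eps, 1.0 - clamp_eps)
    sel = ad.tsum(ad.log(sc[:, :k]), axis=1)
    unsel = ad.tsum(ad.log(1.0 - sc[:, k:]), axis=1)
    return ad.tmean(-(sel + unsel) / n)


def total_loss(
    smooth: Tensor,
    unit_terms: list,
    tpk_terms: list,
    cfg: LossConfig | None = None,
) -> LossReport:
    """Combine the components: ``smooth + sum(unit) + lambda1 * sum(tpk)``."""
    cfg = cfg or LossConfig()
    total = ad.astensor(smooth)
    for u in unit_terms:
        total = total + ad.astensor(u)
    for t in tpk_terms:
        total = total + cfg.lambda1 * ad.astensor(t)
    return LossReport(
        smooth_l1=float(ad.astensor(smooth).data),
        unit=[float(ad.astensor(u).data) for u in unit_terms],
        tpk=[float(ad.astensor(t).data) for t in tpk_terms],
        total=total,
    )
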