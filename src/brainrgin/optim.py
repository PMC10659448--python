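"""First-order optimisation for the tape-based tensors.

Adam with a step learning-rate schedule (multiply by a fixed factor every
``step_epochs`` epochs) is the package default: the training recipe uses
an adaptive optimiser at an initial rate of 1e-3 reduced every 30 epochs.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Adam", "step_lr"]


class Adam:
    """Standard Adam over a named parameter dict."""

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            m = self._m[name] = b1 * self._m[name] + (1 - b1) * g
            v = self._v[name] = b2 * self._v[name] + (1 - b2) * g * g
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def step_lr(lr_init: float, epoch: int, step_epochs: int, factor: float) -> float:
    """Learning rate at a 0-based ``epoch`` under the step schedule.

    Epochs 0..step_epochs-1 run at ``lr_init``, the next block at
    ``lr_init * factor``, and so on.
    """
    if step_epochs <= 0:
        return lr_init
    return lr_init * factor ** (epoch // step_epochs)
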