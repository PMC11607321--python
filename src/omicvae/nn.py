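"""Neural-network building blocks on top of the autodiff engine.

Layers hold their parameters as `Tensor`s with ``requires_grad=True``;
`parameters()` walks them for the optimizer.  Initialization is Glorot
uniform, fully determined by the generator passed at construction.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, matmul, prelu

__all__ = ["Linear", "PReLU", "Dropout", "Sequential", "Adam", "PlateauScheduler"]


class Module:
    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for attr in vars(self).values():
            if isinstance(attr, Tensor) and attr.requires_grad:
                params.append(attr)
            elif isinstance(attr, Module):
                params.extend(attr.parameters())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def train(self, mode: bool = True):
        self.training = mode
        for attr in vars(self).values():
            if isinstance(attr, Module):
                attr.train(mode)
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        if in_features < 1 or out_features < 1:
            raise ValueError(
                f"layer sizes must be positive, got {in_features}x{out_features}"
            )
        bound = np.sqrt(6.0 / (in_features + out_features))
        self.weight = Tensor(
            rng.uniform(-bound, bound, size=(in_features, out_features)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros((1, out_features)), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return matmul(x, self.weight) + self.bias


class PReLU(Module):
    """Parametric rectifier with a single learnable slope (initialized 0.25)."""

    def __init__(self, init: float = 0.25):
        self.slope = Tensor(np.array(init), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return prelu(x, self.slope)


class Dropout(Module):
    """Standard elementwise inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p).astype(np.float64)
        return x * Tensor(keep / (1.0 - self.p))


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """Adam with L2 weight decay added to the gradient."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 3e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1**self.t)
            vhat = self._v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class PlateauScheduler:
    """Reduce-on-plateau: multiply lr by `factor` after `patience` epochs
    without a relative improvement larger than `threshold`; floor at `min_lr`.
    """

    def __init__(
        self,
        optimizer: Adam,
        factor: float = 0.6,
        patience: int = 7,
        threshold: float = 1e-4,
        min_lr: float = 1e-7,
    ):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.threshold = threshold
        self.min_lr = min_lr
        self.best = np.inf
        self.num_bad = 0

    def step(self, metric: float):
        # relative-improvement criterion: better if below best * (1 - threshold)
        if metric < self.best * (1.0 - self.threshold):
            self.best = metric
            self.num_bad = 0
        else:
            self.num_bad += 1
            if self.num_bad > self.patience:
                self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
                self.num_bad = 0

    @property
    def lr(self) -> float:
        return self.optimizer.lr
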