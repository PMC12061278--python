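"""Neural-network building blocks on top of the autodiff tensors."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Module", "Linear", "LayerNorm", "AlphaDropout", "SNNBlock", "Adam"]


class Module:
    """Container with recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        stack: list[object] = [self]
        while stack:
            obj = stack.pop()
            if id(obj) in seen:
                continue
            seen.add(id(obj))
            for v in vars(obj).values():
                if isinstance(v, Tensor) and v.requires_grad:
                    if id(v) not in seen:
                        seen.add(id(v))
                        params.append(v)
                elif isinstance(v, Module):
                    stack.append(v)
                elif isinstance(v, (list, tuple)):
                    stack.extend(m for m in v if isinstance(m, Module))
        return params

    def submodules(self) -> list["Module"]:
        subs: list[Module] = []
        for v in vars(self).values():
            if isinstance(v, Module):
                subs.append(v)
            elif isinstance(v, (list, tuple)):
                subs.extend(m for m in v if isinstance(m, Module))
        return subs

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self.submodules():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- flat state dict for checkpointing ---------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model has {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64).copy()


class Linear(Module):
    """Affine map with lecun-normal initialization (variance 1/fan_in).

    Lecun scaling keeps activation variance near 1 through SELU stacks,
    which is what makes the omics encoder self-normalizing.
    """

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Tensor(rng.normal(0.0, np.sqrt(1.0 / d_in),
                                        size=(d_in, d_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class AlphaDropout(Module):
    """Dropout that preserves the SELU fixed point (zero mean, unit variance).

    Dropped units are set to the SELU saturation value alpha' = -lambda*alpha
    and the output is affinely rescaled so mean/variance are unchanged.
    Identity in eval mode.
    """

    _ALPHA_PRIME = -1.7580993408473766

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        q = 1.0 - self.p
        ap = self._ALPHA_PRIME
        keep = (self.rng.random(x.shape) < q).astype(np.float64)
        a = (q + ap ** 2 * q * self.p) ** -0.5
        b = -a * ap * self.p
        return (x * Tensor(keep) + Tensor((1.0 - keep) * ap)) * a + b


class SNNBlock(Module):
    """Linear -> SELU -> alpha-dropout, the self-normalizing MLP layer."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dropout: float = 0.1):
        super().__init__()
        self.fc = Linear(d_in, d_out, rng)
        self.drop = AlphaDropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.drop(self.fc(x).selu())


class Adam:
    """Adaptive-moment optimizer with decoupled-style L2 weight decay."""

    def __init__(self, params: list[Tensor], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-5):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.wd:
                g = g + self.wd * p.data
            m, v = self.m[i], self.v[i]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            denom = np.sqrt(v / b2t)
            denom += self.eps
            p.data -= (self.lr / b1t) * m / denom

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
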