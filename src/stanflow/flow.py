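"""Conditional normalizing flow over interspike intervals.

The ISI ``tau > 0`` is mapped to the log scale, ``y = log(tau / tau_ref)``,
and pushed through a stack of context-conditioned monotone layers

    y  ->  exp(s(x)) * y + t(x) + sum_j gamma_j(x) * tanh(delta_j(x) * (y - mu_j(x)))

whose parameters are produced by small feedforward networks reading only
the context ``x = [h'; q; t_prev]``.  Each layer is strictly increasing in
``y`` (``gamma_j, delta_j > 0``), so the transform is invertible by
construction and — the target being scalar — the Jacobian is triangular
and its log-determinant is the exact sum of per-layer log-derivatives.
With ``n_bumps=0`` the layers reduce to pure conditional affine maps (the
classic coupling form), under which the model is exactly lognormal; the
saturating terms add the shape flexibility needed to fit skewed ISI laws
such as gamma renewals.  The base density is a standard Gaussian; all
conditioning enters through the transform.

Exact log-likelihoods follow from the change of variables

    log P(tau | x) = log N(z; 0, 1) + log |dz/dtau|,

and sampling inverts the monotone map by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np

from ._autodiff import Tensor
from .attention import AttentionParams

__all__ = [
    "FlowParams",
    "ISIDensityModel",
    "build_context",
    "forward_transform",
    "inverse_transform",
    "log_likelihood",
    "sample_isi",
]

_LOG_2PI = np.log(2.0 * np.pi)
_S_CLAMP = 5.0


@dataclass
class FlowParams:
    """K conditional monotone layers, each driven by a 2-layer MLP."""

    context_dim: int
    n_layers: int = 6
    n_bumps: int = 3
    width: int = 64
    tau_ref: float = 0.050  # seconds; log-transform reference scale
    layers: List[Dict[str, Tensor]] = field(default_factory=list)

    @classmethod
    def init(
        cls,
        context_dim: int,
        n_layers: int = 6,
        n_bumps: int = 3,
        width: int = 64,
        tau_ref: float = 0.050,
        rng: np.random.Generator | int | None = None,
    ) -> "FlowParams":
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        out_dim = 2 + 3 * n_bumps
        k = 1.0 / np.sqrt(context_dim)
        layers = []
        for _ in range(n_layers):
            layers.append(
                {
                    "W1": Tensor(rng.uniform(-k, k, size=(context_dim, width)), requires_grad=True),
                    "b1": Tensor(np.zeros(width), requires_grad=True),
                    # zero-initialized head: the flow starts (near) identity
                    "W2": Tensor(np.zeros((width, out_dim)), requires_grad=True),
                    "b2": Tensor(np.zeros(out_dim), requires_grad=True),
                }
            )
        return cls(
            context_dim=context_dim,
            n_layers=n_layers,
            n_bumps=n_bumps,
            width=width,
            tau_ref=tau_ref,
            layers=layers,
        )

    def parameters(self) -> List[Tensor]:
        return [t for layer in self.layers for t in layer.values()]

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {f"layer{i}.{k}": v.data for i, layer in enumerate(self.layers) for k, v in layer.items()}

    def load_state_dict(self, d: Dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for k, v in layer.items():
                v.data = np.array(d[f"layer{i}.{k}"])


def build_context(context, stimulus_onehot, last_spike_time, trial_duration_s: float = 1.0) -> np.ndarray:
    """Concatenate ``[h'; q; t_prev]`` with ``t_prev`` rescaled to the
    trial-relative unit interval.  Accepts single vectors or batches."""
    h = np.atleast_2d(np.asarray(context, dtype=np.float64))
    q = np.atleast_2d(np.asarray(stimulus_onehot, dtype=np.float64))
    t = np.atleast_1d(np.asarray(last_spike_time, dtype=np.float64)) / trial_duration_s
    if h.shape[0] != q.shape[0] or h.shape[0] != t.shape[0]:
        raise ValueError("context, stimulus one-hot and last spike time must align")
    x = np.concatenate([h, q, t[:, None]], axis=1)
    return x[0] if np.asarray(context).ndim == 1 else x


# ---------------------------------------------------------------------------
# Differentiable core (batched Tensors)
# ---------------------------------------------------------------------------


def _layer_params_t(flow: FlowParams, layer: Dict[str, Tensor], x: Tensor):
    out = (x @ layer["W1"] + layer["b1"]).tanh() @ layer["W2"] + layer["b2"]
    s = out[:, 0:1].clamp(-_S_CLAMP, _S_CLAMP)
    t = out[:, 1:2]
    if flow.n_bumps == 0:
        return s, t, None, None, None
    j = flow.n_bumps
    gam = (out[:, 2 : 2 + j] - 4.0).clamp(-8.0, 3.0).exp()
    dlt = out[:, 2 + j : 2 + 2 * j].clamp(-4.0, 3.0).exp()
    mu = out[:, 2 + 2 * j : 2 + 3 * j]
    return s, t, gam, dlt, mu


def flow_forward_t(flow: FlowParams, y: Tensor, x: Tensor):
    """Map log-ISI ``y`` (B, 1) through all layers given context ``x`` (B, C).

    Returns (z, log_det) Tensors, ``log_det`` being log|dz/dy| (B, 1)."""
    logdet = Tensor(np.zeros((y.shape[0], 1)))
    for layer in flow.layers:
        s, t, gam, dlt, mu = _layer_params_t(flow, layer, x)
        if gam is None:
            y = y * s.exp() + t
            logdet = logdet + s
        else:
            u = ((y - mu) * dlt).tanh()
            y = y * s.exp() + t + (gam * u).sum(axis=1, keepdims=True)
            deriv = s.exp() + (gam * dlt * (1.0 - u * u)).sum(axis=1, keepdims=True)
            logdet = logdet + deriv.log()
    return y, logdet


def _layer_params_np(flow: FlowParams, layer: Dict[str, Tensor], x: np.ndarray):
    out = np.tanh(x @ layer["W1"].data + layer["b1"].data) @ layer["W2"].data + layer["b2"].data
    s = np.clip(out[:, 0], -_S_CLAMP, _S_CLAMP)
    t = out[:, 1]
    if flow.n_bumps == 0:
        return s, t, None, None, None
    j = flow.n_bumps
    gam = np.exp(np.clip(out[:, 2 : 2 + j] - 4.0, -8.0, 3.0))
    dlt = np.exp(np.clip(out[:, 2 + j : 2 + 2 * j], -4.0, 3.0))
    mu = out[:, 2 + 2 * j : 2 + 3 * j]
    return s, t, gam, dlt, mu


def _forward_y_np(flow: FlowParams, y: np.ndarray, x: np.ndarray):
    logdet = np.zeros_like(y)
    for layer in flow.layers:
        s, t, gam, dlt, mu = _layer_params_np(flow, layer, x)
        if gam is None:
            y = y * np.exp(s) + t
            logdet = logdet + s
        else:
            u = np.tanh((y[:, None] - mu) * dlt)
            deriv = np.exp(s) + (gam * dlt * (1.0 - u * u)).sum(axis=1)
            y = y * np.exp(s) + t + (gam * u).sum(axis=1)
            logdet = logdet + np.log(deriv)
    return y, logdet


def _inverse_y_np(flow: FlowParams, z: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Invert the monotone map layer by layer (bisection per layer)."""
    y = z.copy()
    for layer in reversed(flow.layers):
        s, t, gam, dlt, mu = _layer_params_np(flow, layer, x)
        if gam is None:
            y = (y - t) * np.exp(-s)
            continue
        target = y
        # bracket: |bump| <= sum(gam), so invert the affine part with margin
        margin = gam.sum(axis=1)
        lo = (target - t - margin) * np.exp(-s)
        hi = (target - t + margin) * np.exp(-s)
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            val = mid * np.exp(s) + t + (gam * np.tanh((mid[:, None] - mu) * dlt)).sum(axis=1)
            go_right = val < target
            lo = np.where(go_right, mid, lo)
            hi = np.where(go_right, hi, mid)
        y = 0.5 * (lo + hi)
    return y


# ---------------------------------------------------------------------------
# Public numpy API
# ---------------------------------------------------------------------------


def _check_tau(tau) -> np.ndarray:
    tau = np.atleast_1d(np.asarray(tau, dtype=np.float64))
    if np.any(tau <= 0):
        raise ValueError("tau must be strictly positive")
    return tau


def _broadcast_x(x, n: int, context_dim: int) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = np.broadcast_to(x, (n, x.size))
    if x.shape != (n, context_dim):
        raise ValueError(f"context must have shape ({n}, {context_dim}), got {x.shape}")
    return np.ascontiguousarray(x)


def forward_transform(flow: FlowParams, tau, x):
    """Map ISIs to latent space.  Returns ``(z, log_det)`` where ``log_det``
    is the total ``log|dz/dtau|`` including the log-transform Jacobian."""
    tau = _check_tau(tau)
    x = _broadcast_x(x, tau.size, flow.context_dim)
    y = np.log(tau / flow.tau_ref)
    z, logdet_y = _forward_y_np(flow, y, x)
    return z, logdet_y - np.log(tau)


def inverse_transform(flow: FlowParams, z, x):
    """Invert :func:`forward_transform`: latent values back to ISIs."""
    z = np.atleast_1d(np.asarray(z, dtype=np.float64))
    x = _broadcast_x(x, z.size, flow.context_dim)
    y = _inverse_y_np(flow, z, x)
    return flow.tau_ref * np.exp(y)


def log_likelihood(flow: FlowParams, tau, x) -> np.ndarray:
    """Exact conditional log-density ``log P(tau | x)``."""
    z, logdet = forward_transform(flow, tau, x)
    return -0.5 * z**2 - 0.5 * _LOG_2PI + logdet


def sample_isi(flow: FlowParams, x, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` ISIs by sampling the base Gaussian and inverting the flow."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal(n)
    x = _broadcast_x(x, n, flow.context_dim)
    return inverse_transform(flow, z, x)


@dataclass
class ISIDensityModel:
    """Attention encoder + conditional flow for one neuron, with the
    discretization metadata needed to rebuild contexts."""

    attention: AttentionParams
    flow: FlowParams
    bin_ms: float = 1.0
    delta_ms: float = 20.0
    trial_duration_s: float = 3.0

    @property
    def tau_ref(self) -> float:
        return self.flow.tau_ref

    def parameters(self) -> List[Tensor]:
        return self.attention.parameters() + self.flow.parameters()

    def state_dict(self) -> Dict[str, np.ndarray]:
        d = {f"att.{k}": v for k, v in self.attention.state_dict().items()}
        d |= {f"flow.{k}": v for k, v in self.flow.state_dict().items()}
        return d

    def load_state_dict(self, d: Dict[str, np.ndarray]) -> None:
        self.attention.load_state_dict(
            {k[4:]: v for k, v in d.items() if k.startswith("att.")}
        )
        self.flow.load_state_dict({k[5:]: v for k, v in d.items() if k.startswith("flow.")})
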