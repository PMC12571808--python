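"""Spatial-temporal attention encoder over windowed population history.

For each spike of a target unit, the encoder summarizes the ``N x Delta``
population history window that ends at the previous spike:

* a first LSTM (``f1``) scans the window along time; its final hidden
  state drives temporal softmax weights ``alpha`` over the Delta bins;
* a shared affine map embeds each unit's Delta-long history row into a
  ``d``-dimensional vector ``e^m``; per unit, the concatenation
  ``[h*; e^m; q]`` (last hidden state, embedding, stimulus one-hot) is
  mapped to a scalar logit, and sparsemax across units yields spatial
  weights ``beta`` on the simplex with exact zeros;
* the window is reweighted elementwise by the mean-normalized outer
  product ``beta alpha^T`` (multiplication by ``N * Delta``, exact since
  both weight vectors sum to one) and a second LSTM (``f2``) encodes the
  reweighted window into the context vector ``h'`` for the flow.

Sparsemax (the Euclidean projection onto the probability simplex) replaces
softmax spatially so that unsynchronized units receive exactly zero
weight, which is what makes the averaged weights interpretable as a
synchronization summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np

from ._autodiff import Tensor, sparsemax_np

__all__ = [
    "AttentionParams",
    "AttentionOutput",
    "sparsemax",
    "temporal_weights",
    "spatial_weights",
    "reweight_window",
    "encode_context",
    "attention_forward",
]


def sparsemax(logits) -> np.ndarray:
    """Project a logit vector onto the probability simplex (sort-threshold
    algorithm); entries below the threshold are exactly zero."""
    z = np.asarray(logits, dtype=np.float64)
    if z.size == 0:
        raise ValueError("sparsemax of an empty vector is undefined")
    return sparsemax_np(z, axis=-1)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


def _lstm_init(rng: np.random.Generator, input_dim: int, hidden_dim: int) -> Dict[str, Tensor]:
    k = 1.0 / np.sqrt(hidden_dim)
    b = np.zeros(4 * hidden_dim)
    b[hidden_dim : 2 * hidden_dim] = 1.0  # forget-gate bias
    return {
        "Wx": Tensor(rng.uniform(-k, k, size=(input_dim, 4 * hidden_dim)), requires_grad=True),
        "Wh": Tensor(rng.uniform(-k, k, size=(hidden_dim, 4 * hidden_dim)), requires_grad=True),
        "b": Tensor(b, requires_grad=True),
    }


@dataclass
class AttentionParams:
    """All learnable parameters of the encoder for one neuron model."""

    n_units: int
    window_bins: int
    n_stimuli: int
    embed_dim: int = 8
    hidden_dim: int = 32
    f1: Dict[str, Tensor] = field(default_factory=dict)
    f2: Dict[str, Tensor] = field(default_factory=dict)
    We: Tensor = None
    be: Tensor = None
    Walpha: Tensor = None
    balpha: Tensor = None
    Wbeta_h: Tensor = None
    Wbeta_e: Tensor = None
    Wbeta_q: Tensor = None
    bbeta: Tensor = None
    binarize: bool = False

    @classmethod
    def init(
        cls,
        n_units: int,
        window_bins: int,
        n_stimuli: int,
        embed_dim: int = 8,
        hidden_dim: int = 32,
        rng: np.random.Generator | int | None = None,
        binarize: bool = False,
    ) -> "AttentionParams":
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        k_e = 1.0 / np.sqrt(window_bins)
        k_a = 1.0 / np.sqrt(hidden_dim)
        cdim = hidden_dim + embed_dim + n_stimuli
        k_b = 1.0 / np.sqrt(cdim)
        return cls(
            n_units=n_units,
            window_bins=window_bins,
            n_stimuli=n_stimuli,
            embed_dim=embed_dim,
            hidden_dim=hidden_dim,
            f1=_lstm_init(rng, n_units, hidden_dim),
            f2=_lstm_init(rng, n_units, hidden_dim),
            We=Tensor(rng.uniform(-k_e, k_e, size=(window_bins, embed_dim)), requires_grad=True),
            be=Tensor(np.zeros(embed_dim), requires_grad=True),
            Walpha=Tensor(rng.uniform(-k_a, k_a, size=(hidden_dim, window_bins)), requires_grad=True),
            balpha=Tensor(np.zeros(window_bins), requires_grad=True),
            Wbeta_h=Tensor(rng.uniform(-k_b, k_b, size=(hidden_dim, 1)), requires_grad=True),
            Wbeta_e=Tensor(rng.uniform(-k_b, k_b, size=(embed_dim, 1)), requires_grad=True),
            Wbeta_q=Tensor(rng.uniform(-k_b, k_b, size=(n_stimuli, 1)), requires_grad=True),
            bbeta=Tensor(np.zeros(1), requires_grad=True),
            binarize=binarize,
        )

    def parameters(self) -> List[Tensor]:
        ps = [*self.f1.values(), *self.f2.values()]
        ps += self.head_parameters()
        return ps

    def head_parameters(self) -> List[Tensor]:
        """The attention-head parameters (embedding + temporal/spatial
        heads); these sit behind a long, saturating gradient path and are
        typically trained with a larger step size than the encoders."""
        return [
            self.We,
            self.be,
            self.Walpha,
            self.balpha,
            self.Wbeta_h,
            self.Wbeta_e,
            self.Wbeta_q,
            self.bbeta,
        ]

    def state_dict(self) -> Dict[str, np.ndarray]:
        d = {f"f1.{k}": v.data for k, v in self.f1.items()}
        d |= {f"f2.{k}": v.data for k, v in self.f2.items()}
        for name in ("We", "be", "Walpha", "balpha", "Wbeta_h", "Wbeta_e", "Wbeta_q", "bbeta"):
            d[name] = getattr(self, name).data
        return d

    def load_state_dict(self, d: Dict[str, np.ndarray]) -> None:
        for k, v in self.f1.items():
            v.data = np.array(d[f"f1.{k}"])
        for k, v in self.f2.items():
            v.data = np.array(d[f"f2.{k}"])
        for name in ("We", "be", "Walpha", "balpha", "Wbeta_h", "Wbeta_e", "Wbeta_q", "bbeta"):
            getattr(self, name).data = np.array(d[name])


@dataclass
class AttentionOutput:
    alpha: np.ndarray  # (Delta,) temporal weights on the simplex
    beta: np.ndarray  # (N,) spatial weights on the simplex (exact zeros allowed)
    reweighted: np.ndarray  # (N, Delta) mean-normalized reweighted window
    context: np.ndarray  # (hidden_dim,) output of f2
    hidden_last: np.ndarray  # (hidden_dim,) h* from f1
    embedding: np.ndarray  # (N, embed_dim)


# ---------------------------------------------------------------------------
# Forward passes (batched, differentiable)
# ---------------------------------------------------------------------------


def _lstm_run(params: Dict[str, Tensor], window: Tensor, hidden_dim: int) -> tuple:
    """Run an LSTM along the time axis of ``window`` (B, N, Delta).

    Inputs at each step are the length-N population bin vectors.  Returns
    (final hidden state (B, H), list of per-step hidden states).
    """
    b_size = window.shape[0]
    n_steps = window.shape[2]
    h = Tensor(np.zeros((b_size, hidden_dim)))
    c = Tensor(np.zeros((b_size, hidden_dim)))
    hs = []
    for t in range(n_steps):
        x_t = window[:, :, t]
        z = x_t @ params["Wx"] + h @ params["Wh"] + params["b"]
        i = z[:, :hidden_dim].sigmoid()
        f = z[:, hidden_dim : 2 * hidden_dim].sigmoid()
        g = z[:, 2 * hidden_dim : 3 * hidden_dim].tanh()
        o = z[:, 3 * hidden_dim :].sigmoid()
        c = f * c + i * g
        h = o * c.tanh()
        hs.append(h)
    return h, hs


def attention_forward(params: AttentionParams, windows, stim_onehot) -> Dict[str, Tensor]:
    """Differentiable batched forward pass.

    ``windows``: (B, N, Delta) arrays or Tensor; ``stim_onehot``: (B, Q).
    Returns a dict of Tensors: alpha (B, Delta), beta (B, N), reweighted
    (B, N, Delta), context (B, H), hidden_last (B, H), embedding (B, N, d).
    """
    w = windows if isinstance(windows, Tensor) else Tensor(np.asarray(windows, dtype=np.float64))
    if w.ndim != 3 or w.shape[1] != params.n_units or w.shape[2] != params.window_bins:
        raise ValueError(
            f"windows must have shape (B, {params.n_units}, {params.window_bins}), got {w.shape}"
        )
    q = stim_onehot if isinstance(stim_onehot, Tensor) else Tensor(np.asarray(stim_onehot, dtype=np.float64))
    if q.shape[-1] != params.n_stimuli:
        raise ValueError(f"stimulus one-hot must have length {params.n_stimuli}")
    if params.binarize:
        w = Tensor((w.data > 0).astype(np.float64))

    h_last, _ = _lstm_run(params.f1, w, params.hidden_dim)
    alpha = (h_last @ params.Walpha + params.balpha).tanh().softmax()  # (B, Delta)
    emb = w @ params.We + params.be  # (B, N, d)
    # spatial logit per unit: shared affine map of [h*; e^m; q]
    logit = (
        emb @ params.Wbeta_e
        + (h_last @ params.Wbeta_h).reshape(-1, 1, 1)
        + (q @ params.Wbeta_q).reshape(-1, 1, 1)
        + params.bbeta
    )  # (B, N, 1)
    spatial_logits = logit.reshape(logit.shape[0], logit.shape[1]).tanh()  # (B, N)
    beta = spatial_logits.sparsemax()
    n_delta = float(params.n_units * params.window_bins)
    weight = beta.reshape(beta.shape[0], beta.shape[1], 1) * alpha.reshape(alpha.shape[0], 1, alpha.shape[1])
    reweighted = weight * n_delta * w
    context, _ = _lstm_run(params.f2, reweighted, params.hidden_dim)
    return {
        "alpha": alpha,
        "beta": beta,
        "spatial_logits": spatial_logits,
        "reweighted": reweighted,
        "context": context,
        "hidden_last": h_last,
        "embedding": emb,
    }


# ---------------------------------------------------------------------------
# Single-window convenience operations (numpy in / numpy out)
# ---------------------------------------------------------------------------


def temporal_weights(params: AttentionParams, window) -> tuple:
    """Temporal softmax weights for one ``N x Delta`` window.

    Returns (alpha (Delta,), hidden_last (H,), hidden_seq (Delta, H))."""
    w = np.asarray(getattr(window, "window", window), dtype=np.float64)
    if w.shape != (params.n_units, params.window_bins):
        raise ValueError(f"window shape {w.shape} incompatible with params")
    h_last, hs = _lstm_run(params.f1, Tensor(w[None]), params.hidden_dim)
    alpha = (h_last @ params.Walpha + params.balpha).tanh().softmax()
    return alpha.data[0], h_last.data[0], np.stack([h.data[0] for h in hs])


def spatial_weights(params: AttentionParams, hidden_last, embedding, stimulus_onehot) -> np.ndarray:
    """Sparse spatial weights across units from ``h*``, the per-unit
    embeddings and the stimulus one-hot."""
    emb = np.asarray(embedding, dtype=np.float64)
    if emb.ndim != 2 or emb.shape[0] == 0:
        raise ValueError("embedding must be a nonempty N x d matrix")
    h = np.asarray(hidden_last, dtype=np.float64)
    q = np.asarray(stimulus_onehot, dtype=np.float64)
    logits = (
        emb @ params.Wbeta_e.data[:, 0]
        + float(h @ params.Wbeta_h.data[:, 0])
        + float(q @ params.Wbeta_q.data[:, 0])
        + params.bbeta.data[0]
    )
    return sparsemax(np.tanh(logits))


def reweight_window(window, alpha, beta) -> np.ndarray:
    """Mean-normalized spatial-temporal reweighting of one window:
    ``(beta alpha^T / mean(beta alpha^T)) * window`` elementwise, which
    equals multiplication by ``N * Delta`` since both weight vectors sum
    to one."""
    w = np.asarray(getattr(window, "window", window), dtype=np.float64)
    alpha = np.asarray(alpha, dtype=np.float64)
    beta = np.asarray(beta, dtype=np.float64)
    for name, v in (("alpha", alpha), ("beta", beta)):
        if np.any(v < -1e-9) or abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} must lie on the probability simplex")
    n, delta = w.shape
    return (beta[:, None] * alpha[None, :]) * (n * delta) * w


def encode_context(params: AttentionParams, reweighted) -> np.ndarray:
    """Final hidden state of ``f2`` run over a reweighted window."""
    w = np.asarray(reweighted, dtype=np.float64)
    if w.shape != (params.n_units, params.window_bins):
        raise ValueError(f"reweighted window shape {w.shape} incompatible with params")
    h, _ = _lstm_run(params.f2, Tensor(w[None]), params.hidden_dim)
    return h.data[0]


def encode_window(params: AttentionParams, window, stimulus_onehot) -> AttentionOutput:
    """Full encoder pass for a single window (composition of the ops above)."""
    w = np.asarray(getattr(window, "window", window), dtype=np.float64)
    out = attention_forward(params, w[None], np.asarray(stimulus_onehot, dtype=np.float64)[None])
    return AttentionOutput(
        alpha=out["alpha"].data[0],
        beta=out["beta"].data[0],
        reweighted=out["reweighted"].data[0],
        context=out["context"].data[0],
        hidden_last=out["hidden_last"].data[0],
        embedding=out["embedding"].data[0],
    )
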