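"""Per-neuron joint training of the attention encoder and conditional flow.

One model is trained per (unit, trial rotation) by maximizing the exact
ISI log-likelihood over all stimuli jointly (the stimulus one-hot is part
of the conditioning).  The five trials per stimulus rotate through a
train(3) / validation(1) / test(1) scheme; the checkpoint with the best
validation NLL is retained and the test trial is never consulted during
fitting.  Trained models can roll out spike trains autoregressively,
teacher-forced on the other units' held-out histories.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from ._autodiff import Adam, Tensor, concat
from .attention import AttentionParams, attention_forward
from .flow import FlowParams, ISIDensityModel, build_context, flow_forward_t, inverse_transform
from .spike_data import EnsembleRecording, bin_spikes, extract_isis, window_history

logger = logging.getLogger(__name__)

__all__ = [
    "CVSplit",
    "TrainConfig",
    "TrainedNeuronModel",
    "make_splits",
    "build_training_set",
    "train_neuron_model",
    "fit_population",
    "generate_spike_train",
    "evaluate_generation",
    "save_model",
    "load_model",
]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class CVSplit:
    train_trials: Tuple[int, ...]
    val_trial: int
    test_trial: int
    rotation: int

    def __post_init__(self):
        trials = {*self.train_trials, self.val_trial, self.test_trial}
        if len(trials) != len(self.train_trials) + 2:
            raise ValueError("train/val/test trials must be disjoint")


def make_splits(n_trials: int = 5) -> List[CVSplit]:
    """Cyclic trial rotations: rotation ``r`` trains on ``{r, r+1, r+2}``
    (mod n), validates on ``r+3`` and tests on ``r+4``."""
    if n_trials < 3:
        raise ValueError("need at least 3 trials for a train/val/test rotation")
    splits = []
    for r in range(n_trials):
        splits.append(
            CVSplit(
                train_trials=tuple((r + k) % n_trials for k in range(n_trials - 2)),
                val_trial=(r + n_trials - 2) % n_trials,
                test_trial=(r + n_trials - 1) % n_trials,
                rotation=r,
            )
        )
    return splits


@dataclass
class TrainConfig:
    epochs: int = 200
    lr: float = 1e-3
    attention_lr_factor: float = 10.0  # step-size multiplier for the attention heads
    batch_size: int = 64
    delta_ms: float = 20.0
    bin_ms: float = 1.0
    seed: int = 0
    patience: int = 20
    hidden_dim: int = 32
    embed_dim: int = 8
    flow_layers: int = 6
    flow_bumps: int = 3
    flow_width: int = 64
    tau_ref: float = 0.050

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.patience) <= 0 or self.lr <= 0:
            raise ValueError("training hyperparameters must be positive")


@dataclass
class ExampleSet:
    """Vectorized (window, stimulus, t_prev, tau) examples for one unit."""

    windows: np.ndarray  # (M, N, Delta)
    stim_idx: np.ndarray  # (M,)
    t_prev: np.ndarray  # (M,)
    tau: np.ndarray  # (M,)

    def __len__(self) -> int:
        return self.tau.size


def build_training_set(
    rec: EnsembleRecording,
    unit: str,
    trials: Sequence[int],
    delta_ms: float = 20.0,
    bin_ms: float = 1.0,
) -> ExampleSet:
    """One example per ISI of ``unit`` in each (stimulus, trial): the
    population history window ending at the previous spike, the stimulus
    index, the previous spike time and the target interval."""
    if unit not in rec.unit_ids:
        raise KeyError(f"unknown unit {unit!r}")
    u_idx = rec.unit_index(unit)
    windows, stim_idx, t_prev, tau = [], [], [], []
    for q, (sid, _cls) in enumerate(rec.stimuli):
        for trial in trials:
            seq = extract_isis(rec, unit, sid, trial)
            if len(seq.isis) == 0:
                continue
            binned = bin_spikes(rec, sid, trial, bin_ms)
            for t_k, tau_k in zip(seq.last_spike_times, seq.isis):
                w = window_history(binned, u_idx, t_k, delta_ms)
                windows.append(w.window)
                stim_idx.append(q)
                t_prev.append(t_k)
                tau.append(tau_k)
    n, d = rec.n_units, int(round(delta_ms / bin_ms))
    return ExampleSet(
        windows=np.asarray(windows, dtype=np.float64).reshape(-1, n, d),
        stim_idx=np.asarray(stim_idx, dtype=np.int64),
        t_prev=np.asarray(t_prev, dtype=np.float64),
        tau=np.asarray(tau, dtype=np.float64),
    )


@dataclass
class TrainedNeuronModel:
    unit: str
    split: CVSplit
    model: ISIDensityModel
    val_nll: float
    history: List[Dict[str, float]] = field(default_factory=list)


def _onehot(idx: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((idx.size, n))
    out[np.arange(idx.size), idx] = 1.0
    return out


def _batch_nll_t(model: ISIDensityModel, rec, ex: ExampleSet, idx: np.ndarray):
    """Differentiable mean NLL over the examples ``idx`` (constant terms
    from the log-transform Jacobian included)."""
    q = _onehot(ex.stim_idx[idx], rec.n_stimuli)
    att = attention_forward(model.attention, ex.windows[idx], q)
    x = concat(
        [
            att["context"],
            Tensor(q),
            Tensor((ex.t_prev[idx] / model.trial_duration_s)[:, None]),
        ],
        axis=1,
    )
    tau = ex.tau[idx]
    y = Tensor(np.log(tau / model.tau_ref)[:, None])
    z, logdet_y = flow_forward_t(model.flow, y, x)
    loss = (z * z * 0.5 - logdet_y).mean()
    const = 0.5 * _LOG_2PI + float(np.mean(np.log(tau)))
    return loss, const


def _eval_nll(model: ISIDensityModel, rec, ex: ExampleSet) -> float:
    loss, const = _batch_nll_t(model, rec, ex, np.arange(len(ex)))
    return float(loss.data) + const


def train_neuron_model(
    rec: EnsembleRecording,
    unit: str,
    split: CVSplit,
    config: TrainConfig,
) -> TrainedNeuronModel:
    """Maximum-likelihood fit of one neuron's attention+flow model on the
    split's training trials, selecting the checkpoint with the best
    validation NLL."""
    train_ex = build_training_set(rec, unit, split.train_trials, config.delta_ms, config.bin_ms)
    if len(train_ex) == 0:
        raise ValueError(f"unit {unit!r} has no training examples (fewer than 2 spikes per trial)")
    val_ex = build_training_set(rec, unit, (split.val_trial,), config.delta_ms, config.bin_ms)

    seed = abs(hash((config.seed, rec.unit_index(unit), split.rotation))) % (2**31)
    rng = np.random.default_rng(seed)
    delta_bins = int(round(config.delta_ms / config.bin_ms))
    attention = AttentionParams.init(
        rec.n_units,
        delta_bins,
        rec.n_stimuli,
        embed_dim=config.embed_dim,
        hidden_dim=config.hidden_dim,
        rng=rng,
    )
    flow = FlowParams.init(
        context_dim=config.hidden_dim + rec.n_stimuli + 1,
        n_layers=config.flow_layers,
        n_bumps=config.flow_bumps,
        width=config.flow_width,
        tau_ref=config.tau_ref,
        rng=rng,
    )
    model = ISIDensityModel(
        attention=attention,
        flow=flow,
        bin_ms=config.bin_ms,
        delta_ms=config.delta_ms,
        trial_duration_s=rec.trial_duration_s,
    )
    params = model.parameters()
    heads = {id(p) for p in attention.head_parameters()}
    lrs = [config.lr * (config.attention_lr_factor if id(p) in heads else 1.0) for p in params]
    opt = Adam(params, lr=config.lr, lrs=lrs)
    best_state, best_val, best_epoch = copy.deepcopy(model.state_dict()), np.inf, -1
    history: List[Dict[str, float]] = []
    m = len(train_ex)
    for epoch in range(config.epochs):
        order = rng.permutation(m)
        train_nll = 0.0
        for start in range(0, m, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, const = _batch_nll_t(model, rec, train_ex, idx)
            opt.zero_grad()
            loss.backward()
            opt.step()
            train_nll += (float(loss.data) + const) * idx.size
        train_nll /= m
        val_nll = _eval_nll(model, rec, val_ex) if len(val_ex) else train_nll
        history.append({"epoch": epoch, "train_nll": train_nll, "val_nll": val_nll})
        if val_nll < best_val - 1e-9:
            best_val, best_epoch = val_nll, epoch
            best_state = copy.deepcopy(model.state_dict())
        elif epoch - best_epoch >= config.patience:
            break
    model.load_state_dict(best_state)
    return TrainedNeuronModel(unit=unit, split=split, model=model, val_nll=best_val, history=history)


def fit_population(
    rec: EnsembleRecording,
    config: TrainConfig,
    rotations: Sequence[int] = (0,),
    units: Optional[Sequence[str]] = None,
    n_trials: Optional[int] = None,
) -> Dict[str, List[TrainedNeuronModel]]:
    """Train one model per (unit, rotation); the evaluation driver for the
    synchronization summary."""
    units = list(units) if units is not None else list(rec.unit_ids)
    splits = make_splits(n_trials or rec.trials_per_stimulus)
    out: Dict[str, List[TrainedNeuronModel]] = {}
    for unit in units:
        out[unit] = []
        for r in rotations:
            out[unit].append(train_neuron_model(rec, unit, splits[r], config))
            logger.info("trained %s rotation %d: val NLL %.4f", unit, r, out[unit][-1].val_nll)
    return out


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------


def save_model(trained: TrainedNeuronModel, path) -> None:
    """Write one neuron model as ``<path>.npz`` (weights) plus
    ``<path>.json`` (architecture + split metadata)."""
    import json
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), **trained.model.state_dict())
    att, fl = trained.model.attention, trained.model.flow
    meta = {
        "unit": trained.unit,
        "split": {
            "train_trials": list(trained.split.train_trials),
            "val_trial": trained.split.val_trial,
            "test_trial": trained.split.test_trial,
            "rotation": trained.split.rotation,
        },
        "val_nll": trained.val_nll,
        "n_units": att.n_units,
        "window_bins": att.window_bins,
        "n_stimuli": att.n_stimuli,
        "embed_dim": att.embed_dim,
        "hidden_dim": att.hidden_dim,
        "flow": {
            "context_dim": fl.context_dim,
            "n_layers": fl.n_layers,
            "n_bumps": fl.n_bumps,
            "width": fl.width,
            "tau_ref": fl.tau_ref,
        },
        "bin_ms": trained.model.bin_ms,
        "delta_ms": trained.model.delta_ms,
        "trial_duration_s": trained.model.trial_duration_s,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_model(path) -> TrainedNeuronModel:
    """Load a neuron model written by :func:`save_model`."""
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    attention = AttentionParams.init(
        meta["n_units"],
        meta["window_bins"],
        meta["n_stimuli"],
        embed_dim=meta["embed_dim"],
        hidden_dim=meta["hidden_dim"],
        rng=0,
    )
    flow = FlowParams.init(rng=0, **meta["flow"])
    model = ISIDensityModel(
        attention=attention,
        flow=flow,
        bin_ms=meta["bin_ms"],
        delta_ms=meta["delta_ms"],
        trial_duration_s=meta["trial_duration_s"],
    )
    with np.load(path.with_suffix(".npz")) as archive:
        model.load_state_dict(dict(archive))
    split = CVSplit(
        train_trials=tuple(meta["split"]["train_trials"]),
        val_trial=meta["split"]["val_trial"],
        test_trial=meta["split"]["test_trial"],
        rotation=meta["split"]["rotation"],
    )
    return TrainedNeuronModel(unit=meta["unit"], split=split, model=model, val_nll=meta["val_nll"])


# ---------------------------------------------------------------------------
# Generation and evaluation
# ---------------------------------------------------------------------------


def generate_spike_train(
    trained: TrainedNeuronModel,
    rec: EnsembleRecording,
    stimulus: str,
    duration_s: Optional[float] = None,
    seed=None,
    max_spikes: int = 100_000,
) -> np.ndarray:
    """Autoregressive rollout for the trained unit under ``stimulus``.

    Other units' histories are teacher-forced from the split's held-out
    test trial; the target unit's own row is updated with the generated
    spikes.  Conditioning starts at trial onset (t_prev = 0, zero-padded
    window)."""
    model = trained.model
    duration = duration_s if duration_s is not None else rec.trial_duration_s
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u_idx = rec.unit_index(trained.unit)
    q = np.zeros(rec.n_stimuli)
    q[rec.stimulus_index(stimulus)] = 1.0
    binned = bin_spikes(rec, stimulus, trained.split.test_trial, model.bin_ms)
    counts = binned.counts.astype(np.float64)
    counts[u_idx] = 0.0
    binned.counts = counts
    out: List[float] = []
    t = 0.0
    while True:
        w = window_history(binned, u_idx, min(t, duration), model.delta_ms)
        att = attention_forward(model.attention, w.window[None], q[None])
        x = build_context(att["context"].data[0], q, t, model.trial_duration_s)
        z = rng.standard_normal(1)
        tau = float(inverse_transform(model.flow, z, x)[0])
        t = t + tau
        if t > duration:
            break
        out.append(t)
        if len(out) > max_spikes:
            raise RuntimeError(f"generation runaway: more than {max_spikes} spikes")
        j = min(int(t / (model.bin_ms / 1000.0)), counts.shape[1] - 1)
        counts[u_idx, j] += 1.0
    return np.asarray(out)


def evaluate_generation(
    empirical_isis,
    generated_isis,
    empirical_rates,
    generated_rates,
    ri_empirical=None,
    ri_generated=None,
) -> Dict[str, float]:
    """Generation-fidelity report: two-sample KS on ISIs, two-sided t-test
    on per-trial firing rates and (optionally) the correlation between
    empirical and generated response-index vectors."""
    emp = np.asarray(empirical_isis, dtype=np.float64)
    gen = np.asarray(generated_isis, dtype=np.float64)
    if emp.size < 2 or gen.size < 2:
        raise ValueError("need at least 2 ISI samples on both sides")
    ks = stats.ks_2samp(emp, gen)
    tt = stats.ttest_ind(np.asarray(empirical_rates, float), np.asarray(generated_rates, float))
    report = {
        "ks_stat": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "t_stat": float(tt.statistic),
        "t_pvalue": float(tt.pvalue),
    }
    if ri_empirical is not None and ri_generated is not None:
        r = np.corrcoef(np.asarray(ri_empirical, float), np.asarray(ri_generated, float))[0, 1]
        report["ri_correlation"] = float(r)
    return report
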