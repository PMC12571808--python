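"""Synchronization quantification and stimulus-clustering evaluation.

Three routes to a per-stimulus synchronization description are provided:

* **STA** — the spatial-attention summary matrix ``B`` (Q stimuli x N
  units): spatial weights averaged over all spikes of each unit, over
  trial rotations, then across units.  Rows are simplex vectors.
* **ESI** — the classic shift-predictor-corrected cross-correlogram
  synchronization index: coincident events in the central +/- delta/2
  peak, chance-corrected by averaging four trial shifts, normalized by
  the two units' spike counts in the analysis window, in percent.
* **KB** — kernelized binless similarity: cosine similarity between the
  two trains convolved with a causal exponential kernel exp(-t/phi)u(t),
  likewise shift-corrected.

Feature matrices from any route feed a common evaluation: t-SNE to 2-D,
2-means, and accuracy against the behavioral / non-behavioral annotation
under the best label permutation.  Unit-ablation and dissimilarity-index
analyses operate on the summary matrix directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .attention import attention_forward
from .spike_data import EnsembleRecording
from .training import TrainedNeuronModel, build_training_set

logger = logging.getLogger(__name__)

__all__ = [
    "SyncSummary",
    "AttentionLogitCache",
    "PairwiseSyncMatrix",
    "ClusterReport",
    "attention_summary",
    "build_logit_cache",
    "summary_from_cache",
    "esi",
    "kernelized_binless",
    "pairwise_matrix",
    "upper_triangular_features",
    "cluster_stimuli",
    "ablation_accuracy",
    "response_index",
    "psth_zscore",
    "dissimilarity_index",
]


# ---------------------------------------------------------------------------
# Spatial-attention summary
# ---------------------------------------------------------------------------


@dataclass
class SyncSummary:
    """Q x N synchronization summary matrix B and its per-neuron parts."""

    B: np.ndarray
    per_neuron: List[np.ndarray]
    stimulus_ids: List[str]
    unit_ids: List[str]


@dataclass
class AttentionLogitCache:
    """Per-spike spatial logits (pre-sparsemax) for every unit model.

    Caching the logits makes unit-ablation counterfactuals cheap: the
    per-unit logit is computed independently of the other units, so
    removing units from the ensemble only changes which logits compete in
    the sparsemax, not the logits themselves.
    """

    records: List[Tuple[str, np.ndarray, np.ndarray]]  # (unit, logits (M, N), stim_idx (M,))
    stimulus_ids: List[str]
    unit_ids: List[str]


def build_logit_cache(
    models: Dict[str, List[TrainedNeuronModel]],
    rec: EnsembleRecording,
    eval_trials: str = "all",
) -> AttentionLogitCache:
    """One forward pass per (unit, rotation): collect each spike's spatial
    logits.

    ``eval_trials`` selects which trials contribute spikes: ``"all"``
    (default — the summary is an interpretability readout, and averaging
    over every spike minimizes its variance; the test trial is still never
    used for model fitting or selection), ``"val"``, ``"test"`` or
    ``"val+test"``."""
    records = []
    for unit in [u for u in rec.unit_ids if u in models]:
        for trained in models[unit]:
            trials = {
                "val": (trained.split.val_trial,),
                "test": (trained.split.test_trial,),
                "val+test": (trained.split.val_trial, trained.split.test_trial),
                "all": tuple(range(rec.trials_per_stimulus)),
            }[eval_trials]
            ex = build_training_set(
                rec, unit, trials, trained.model.delta_ms, trained.model.bin_ms
            )
            if len(ex) == 0:
                logger.warning("unit %s has no spikes in evaluation trials", unit)
                continue
            onehot = np.zeros((len(ex), rec.n_stimuli))
            onehot[np.arange(len(ex)), ex.stim_idx] = 1.0
            att = attention_forward(trained.model.attention, ex.windows, onehot)
            records.append((unit, att["spatial_logits"].data, ex.stim_idx.copy()))
    return AttentionLogitCache(
        records=records, stimulus_ids=list(rec.stimulus_ids), unit_ids=list(rec.unit_ids)
    )


def summary_from_cache(
    cache: AttentionLogitCache, remove_units: Sequence[str] = ()
) -> SyncSummary:
    """Summary matrix over the units NOT in ``remove_units``: sparsemax is
    re-applied across the surviving units' logits (removed units no
    longer compete for attention), then averaged over spikes, rotations
    and units as usual."""
    removed = set(remove_units)
    keep = [i for i, u in enumerate(cache.unit_ids) if u not in removed]
    if not keep:
        raise ValueError("cannot remove every unit")
    kept_ids = [cache.unit_ids[i] for i in keep]
    q_count = len(cache.stimulus_ids)
    per_unit_acc: Dict[str, np.ndarray] = {}
    per_unit_cnt: Dict[str, np.ndarray] = {}
    from ._autodiff import sparsemax_np

    for unit, logits, stim_idx in cache.records:
        if unit in removed:
            continue
        beta = sparsemax_np(logits[:, keep], axis=-1)
        acc = per_unit_acc.setdefault(unit, np.zeros((q_count, len(keep))))
        cnt = per_unit_cnt.setdefault(unit, np.zeros(q_count))
        for q in range(q_count):
            mask = stim_idx == q
            if not mask.any():
                logger.warning(
                    "unit %s has no spikes under stimulus %s; contribution skipped",
                    unit,
                    cache.stimulus_ids[q],
                )
                continue
            acc[q] += beta[mask].mean(axis=0)
            cnt[q] += 1
    per_neuron = []
    for unit in kept_ids:
        if unit not in per_unit_acc:
            continue
        bn = np.full((q_count, len(keep)), np.nan)
        nonzero = per_unit_cnt[unit] > 0
        bn[nonzero] = per_unit_acc[unit][nonzero] / per_unit_cnt[unit][nonzero, None]
        per_neuron.append(bn)
    stacked = np.stack(per_neuron)
    with np.errstate(invalid="ignore"):
        B = np.nanmean(stacked, axis=0)
    return SyncSummary(
        B=B, per_neuron=per_neuron, stimulus_ids=list(cache.stimulus_ids), unit_ids=kept_ids
    )


def attention_summary(
    models: Dict[str, List[TrainedNeuronModel]],
    rec: EnsembleRecording,
    eval_trials: str = "all",
) -> SyncSummary:
    """Average spatial-attention weights over all spikes, over rotations,
    and over units, into the summary matrix B (see
    :func:`build_logit_cache` for the ``eval_trials`` convention)."""
    return summary_from_cache(build_logit_cache(models, rec, eval_trials))


# ---------------------------------------------------------------------------
# Pairwise indices
# ---------------------------------------------------------------------------


def _coincidences(train1: np.ndarray, train2: np.ndarray, half_width_s: float) -> int:
    """Number of spike pairs with |t1 - t2| <= half_width_s (the central
    cross-correlogram peak)."""
    if train1.size == 0 or train2.size == 0:
        return 0
    lags = train1[:, None] - train2[None, :]
    return int(np.count_nonzero(np.abs(lags) <= half_width_s))


def esi(
    train1,
    train2,
    shuffle_trains: Sequence[np.ndarray],
    delta_ms: float = 5.0,
    T_ms: float = 1000.0,
    bin_ms: float = 1.0,
) -> float:
    """Shift-predictor-corrected synchronization index in percent.

    ``train1``/``train2`` are the two units' spike times (s) inside the
    analysis window (T ms after stimulus onset); ``shuffle_trains`` are
    the second unit's trains from other trials (the shift predictor).
    """
    t1 = np.asarray(train1, dtype=np.float64)
    t2 = np.asarray(train2, dtype=np.float64)
    if t1.size == 0 or t2.size == 0:
        raise ValueError("ESI is undefined for an empty spike train")
    half = delta_ms / 2.0 / 1000.0
    ce_raw = _coincidences(t1, t2, half)
    shuffles = [np.asarray(s, dtype=np.float64) for s in shuffle_trains]
    if not shuffles:
        raise ValueError("shift predictor requires at least one shuffle train")
    ce_shuffle = float(np.mean([_coincidences(t1, s, half) for s in shuffles]))
    return (ce_raw - ce_shuffle) / (t1.size + t2.size) * 100.0


def _smooth_on_grid(train: np.ndarray, t0: float, n: int, dt: float, phi: float) -> np.ndarray:
    """Causal exponential filtering of a spike train sampled on a fine grid."""
    sig = np.zeros(n)
    decay = np.exp(-dt * np.arange(n) / phi)
    for t in train:
        j = int(np.ceil((t - t0) / dt - 1e-12))
        if j < 0:
            sig += np.exp((t - t0) / phi) * decay[: n]  # spike before grid start
        elif j < n:
            sig[j:] += np.exp(-((t0 + j * dt) - t) / phi) * decay[: n - j]
    return sig


def kernelized_binless(train1, train2, phi_ms: float = 5.0, grid_ms: float = 0.1) -> float:
    """Cosine similarity of the exponentially kernelized trains, in [0, 1].

    A train with zero spikes yields similarity 0 by convention."""
    t1 = np.asarray(train1, dtype=np.float64)
    t2 = np.asarray(train2, dtype=np.float64)
    if t1.size == 0 or t2.size == 0:
        return 0.0
    phi = phi_ms / 1000.0
    dt = grid_ms / 1000.0
    t0 = min(t1.min(), t2.min())
    t_end = max(t1.max(), t2.max()) + 12.0 * phi
    n = int(np.ceil((t_end - t0) / dt)) + 1
    s1 = _smooth_on_grid(t1, t0, n, dt, phi)
    s2 = _smooth_on_grid(t2, t0, n, dt, phi)
    denom = np.linalg.norm(s1) * np.linalg.norm(s2)
    return float(s1 @ s2 / denom) if denom > 0 else 0.0


@dataclass
class PairwiseSyncMatrix:
    """Per-stimulus symmetric N x N matrix of pairwise SI values."""

    matrices: Dict[str, np.ndarray]
    method: str
    params: Dict[str, float] = field(default_factory=dict)
    unit_ids: List[str] = field(default_factory=list)


def _window_train(rec: EnsembleRecording, unit: str, stim: str, trial: int, t0: float, t1: float):
    t = rec.get_spikes(unit, stim, trial)
    return t[(t >= t0) & (t < t1)]


def pairwise_matrix(
    rec: EnsembleRecording,
    method: str = "esi",
    delta_ms: float = 5.0,
    T_ms: float = 1000.0,
    phi_ms: float = 5.0,
    grid_ms: float = 0.1,
    raw_trial: int = 0,
) -> PairwiseSyncMatrix:
    """All unit pairs scored per stimulus.  Trial ``raw_trial`` is the raw
    pairing; the remaining trials serve as the shift predictor."""
    if rec.n_units < 2:
        raise ValueError("need at least 2 units")
    method = method.lower()
    if method not in ("esi", "kb"):
        raise ValueError("method must be 'esi' or 'kb'")
    t0 = rec.stim_onset_s
    t1 = t0 + T_ms / 1000.0
    shuffle_trials = [t for t in range(rec.trials_per_stimulus) if t != raw_trial]
    matrices: Dict[str, np.ndarray] = {}
    for sid in rec.stimulus_ids:
        mat = np.full((rec.n_units, rec.n_units), np.nan)
        trains = {
            (u, tr): _window_train(rec, u, sid, tr, t0, t1)
            for u in rec.unit_ids
            for tr in range(rec.trials_per_stimulus)
        }
        for i, ui in enumerate(rec.unit_ids):
            for j in range(i + 1, rec.n_units):
                uj = rec.unit_ids[j]
                try:
                    if method == "esi":
                        val = esi(
                            trains[(ui, raw_trial)],
                            trains[(uj, raw_trial)],
                            [trains[(uj, tr)] for tr in shuffle_trials],
                            delta_ms=delta_ms,
                            T_ms=T_ms,
                        )
                    else:
                        raw = kernelized_binless(
                            trains[(ui, raw_trial)], trains[(uj, raw_trial)], phi_ms, grid_ms
                        )
                        shuf = np.mean(
                            [
                                kernelized_binless(
                                    trains[(ui, raw_trial)], trains[(uj, tr)], phi_ms, grid_ms
                                )
                                for tr in shuffle_trials
                            ]
                        )
                        val = raw - shuf
                except ValueError as err:
                    logger.warning("pair (%s, %s) under %s skipped: %s", ui, uj, sid, err)
                    continue
                mat[i, j] = mat[j, i] = val
        matrices[sid] = mat
    params = {"delta_ms": delta_ms, "T_ms": T_ms} if method == "esi" else {"phi_ms": phi_ms}
    return PairwiseSyncMatrix(matrices=matrices, method=method, params=params, unit_ids=list(rec.unit_ids))


def upper_triangular_features(sync: PairwiseSyncMatrix, stimulus_ids: Sequence[str]) -> np.ndarray:
    """Stack the upper-triangular vectorization of each stimulus matrix
    into a Q x (N choose 2) feature matrix (missing entries -> 0)."""
    n = len(sync.unit_ids)
    iu = np.triu_indices(n, k=1)
    rows = []
    for sid in stimulus_ids:
        v = sync.matrices[sid][iu]
        rows.append(np.nan_to_num(v, nan=0.0))
    return np.asarray(rows)


# ---------------------------------------------------------------------------
# Clustering evaluation
# ---------------------------------------------------------------------------


@dataclass
class ClusterReport:
    method: str
    mean_accuracy: float
    sd_accuracy: float
    accuracies: List[float]
    seeds: List[int]
    embedding: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None


def _two_class_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    agree = float(np.mean(pred == truth))
    return max(agree, 1.0 - agree)


def cluster_stimuli(
    features: np.ndarray,
    class_labels: Sequence[str],
    n_seeds: int = 10,
    seed: int = 0,
    use_tsne: bool = True,
    method: str = "",
) -> ClusterReport:
    """t-SNE to 2-D (perplexity min(5, Q-1)) then 2-means; accuracy is the
    best-permutation agreement with the binary behavioral annotation,
    repeated over ``n_seeds`` random initializations."""
    X = np.asarray(features, dtype=np.float64)
    q = X.shape[0]
    if q < 4:
        raise ValueError("need at least 4 stimuli to cluster")
    truth = np.asarray([1 if c == "behavioral" else 0 for c in class_labels])
    if truth.min() == truth.max():
        raise ValueError("both stimulus classes must be present")
    accs, last_emb, last_lab = [], None, None
    seeds = [seed + k for k in range(n_seeds)]
    for s in seeds:
        emb = X
        if use_tsne:
            emb = TSNE(
                n_components=2,
                perplexity=min(5, q - 1),
                max_iter=1000,
                init="random",
                random_state=s,
            ).fit_transform(X)
        km = KMeans(n_clusters=2, n_init=10, random_state=s).fit(emb)
        accs.append(_two_class_accuracy(km.labels_, truth))
        last_emb, last_lab = emb, km.labels_
    return ClusterReport(
        method=method,
        mean_accuracy=float(np.mean(accs)),
        sd_accuracy=float(np.std(accs)),
        accuracies=[float(a) for a in accs],
        seeds=seeds,
        embedding=last_emb,
        labels=last_lab,
    )


def ablation_accuracy(
    source,
    class_labels: Sequence[str],
    remove_units: Sequence[str] = (),
    n_seeds: int = 10,
    seed: int = 0,
    use_tsne: bool = True,
    renormalize: bool = False,
) -> ClusterReport:
    """Clustering accuracy after removing units from the summary.

    Preferred input is an :class:`AttentionLogitCache`: the spatial
    weights are then *recomputed* by sparsemax over the surviving units'
    logits, the honest counterfactual in which removed units no longer
    compete for attention.  Passing a :class:`SyncSummary` instead falls
    back to plain column deletion of B (with ``renormalize=True``
    re-projecting rows onto the simplex).  Column surgery cannot localize
    attribution: rows of B are simplex vectors, so every column carries
    the class signal of the others as its complement."""
    if isinstance(source, AttentionLogitCache):
        summary = summary_from_cache(source, remove_units)
        B = summary.B
        if not set(remove_units) <= set(source.unit_ids):
            raise KeyError("unknown unit in remove_units")
    else:
        summary = source
        keep = [i for i, u in enumerate(summary.unit_ids) if u not in set(remove_units)]
        if not keep:
            raise ValueError("cannot remove every unit")
        B = summary.B[:, keep]
        if renormalize:
            row_sums = B.sum(axis=1, keepdims=True)
            B = np.where(
                row_sums > 0, B / np.where(row_sums > 0, row_sums, 1.0), 1.0 / B.shape[1]
            )
    return cluster_stimuli(
        B, class_labels, n_seeds=n_seeds, seed=seed, use_tsne=use_tsne, method="sta-ablate"
    )


# ---------------------------------------------------------------------------
# Rate-based descriptors
# ---------------------------------------------------------------------------


def _stim_rate(rec: EnsembleRecording, unit: str, sid: str, window_s: float = 0.6) -> float:
    """Firing rate over the stimulation period (0..window_s after onset),
    averaged over trials."""
    t0, t1 = rec.stim_onset_s, rec.stim_onset_s + window_s
    counts = [
        np.count_nonzero(
            (rec.get_spikes(unit, sid, tr) >= t0) & (rec.get_spikes(unit, sid, tr) < t1)
        )
        for tr in range(rec.trials_per_stimulus)
    ]
    return float(np.mean(counts)) / window_s


def response_index(rec: EnsembleRecording, unit: str, odor: str, window_s: float = 0.6) -> float:
    """Baseline- and control-corrected, SD-normalized evoked-rate score:
    ``RI = ((r_odor - r_control) - r_mean) / SD`` with rates over the
    0-600 ms post-onset window and mean/SD taken across all stimuli."""
    controls = [sid for sid, cls in rec.stimuli if cls == "control"]
    if not controls:
        raise ValueError("recording has no control stimulus")
    if rec.n_stimuli < 2:
        raise ValueError("need at least 2 stimuli for the rate SD")
    rates = {sid: _stim_rate(rec, unit, sid, window_s) for sid in rec.stimulus_ids}
    r_control = float(np.mean([rates[c] for c in controls]))
    all_rates = np.array(list(rates.values()))
    sd = float(np.std(all_rates, ddof=1))
    if sd == 0:
        raise ValueError("zero rate SD across stimuli; RI undefined")
    return ((rates[odor] - r_control) - float(all_rates.mean())) / sd


def psth_zscore(
    rec: EnsembleRecording,
    unit: str,
    stimulus: str,
    bin_ms: float = 20.0,
    smooth_sd_bins: float = 3.0,
    baseline_ms: float = 200.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Trial-averaged, Gaussian-smoothed PSTH z-scored against the
    pre-onset baseline.  Returns (bin centers in s, z values)."""
    bin_s = bin_ms / 1000.0
    n_bins = int(np.ceil(rec.trial_duration_s / bin_s - 1e-9))
    edges = np.arange(n_bins + 1) * bin_s
    counts = np.zeros(n_bins)
    for tr in range(rec.trials_per_stimulus):
        c, _ = np.histogram(rec.get_spikes(unit, stimulus, tr), bins=edges)
        counts += c
    psth = counts / rec.trials_per_stimulus / bin_s  # Hz
    # reflected edges: a constant-rate train then stays flat at the trial ends
    smoothed = gaussian_filter1d(psth, sigma=smooth_sd_bins, mode="reflect", truncate=3.0)
    base_mask = (edges[1:] <= rec.stim_onset_s + 1e-9) & (
        edges[:-1] >= rec.stim_onset_s - baseline_ms / 1000.0 - 1e-9
    )
    if base_mask.sum() < 2:
        raise ValueError("baseline window contains fewer than 2 bins")
    # baseline statistics from the raw (unsmoothed) PSTH: the z values are
    # in units of the SD of spontaneous activity, not of the smoothed trace
    mu = psth[base_mask].mean()
    sigma = psth[base_mask].std(ddof=1)
    if sigma == 0:
        raise ValueError("zero baseline variance; record a longer baseline")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, (smoothed - mu) / sigma


def dissimilarity_index(
    summary: SyncSummary, reference: str, comparisons: Sequence[str]
) -> Dict[str, float]:
    """Euclidean distances between the reference stimulus row of B and
    each comparison row, normalized by their mean."""
    if len(comparisons) < 2:
        raise ValueError("need at least 2 comparison stimuli")
    idx = {s: i for i, s in enumerate(summary.stimulus_ids)}
    ref = summary.B[idx[reference]]
    raw = np.array([np.linalg.norm(summary.B[idx[c]] - ref) for c in comparisons])
    return dict(zip(comparisons, raw / raw.mean()))
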