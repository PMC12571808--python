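"""Burst-based classification of units into putative PN and LN types.

Projection neurons (PNs) in the antennal lobe tend to fire in bursts
during spontaneous activity, while local interneurons (LNs) fire
regularly.  Bursts are detected with the Poisson-Surprise criterion: the
surprise of a spike set is the negative log-probability that a Poisson
process at the train's mean rate produces at least that many spikes in
the set's time span.  Candidate bursts are seeded by unusually short
ISIs, grown and pruned greedily to maximize the surprise, and kept if
they contain at least three spikes.

Six burst features summarize each unit's 5 s of spontaneous activity and
feed a logistic classifier.  Following the original procedure, the train
and test feature sets are min-max scaled with *separate* scalers (a flag
restores conventional train-bounds scaling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .spike_data import EnsembleRecording

logger = logging.getLogger(__name__)

__all__ = [
    "Burst",
    "BurstFeatures",
    "NeuronTypeModel",
    "poisson_surprise",
    "detect_bursts",
    "burst_features",
    "spontaneous_segment",
    "fit_type_classifier",
    "classify",
]

FEATURE_NAMES = (
    "within_burst_max_freq",
    "within_burst_n_spikes",
    "pct_burst_spikes",
    "burst_freq",
    "mean_surprise",
    "max_surprise",
)


def poisson_surprise(n_spikes: int, rate_r: float, span_T: float) -> float:
    """Poisson Surprise ``S = rT - log sum_{j>=n} (rT)^j / j!`` of observing
    at least ``n_spikes`` events in ``span_T`` at rate ``rate_r``,
    evaluated through the Poisson survival function for stability."""
    mu = rate_r * span_T
    if mu <= 0:
        raise ValueError("rate_r * span_T must be positive")
    if n_spikes <= 0:
        return 0.0
    s = -stats.poisson.logsf(n_spikes - 1, mu)
    return float(max(s, 0.0))


@dataclass
class Burst:
    start_index: int
    end_index: int  # inclusive
    start_time: float
    end_time: float
    n_spikes: int
    surprise: float


def _set_surprise(times: np.ndarray, i: int, j: int, rate: float) -> float:
    span = times[j] - times[i]
    if span <= 0:
        return 0.0
    return poisson_surprise(j - i + 1, rate, span)


def detect_bursts(spike_times, p: float = 0.2, rate: Optional[float] = None) -> List[Burst]:
    """Poisson-Surprise burst detection.

    Seed pairs are successive spikes with ISI below ``p`` times the mean
    ISI; each seed is extended forward one spike at a time while the
    surprise strictly increases, then pruned from the front under the
    same rule.  Sets with >= 3 spikes are kept; overlapping sets merge.
    """
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    t = np.asarray(spike_times, dtype=np.float64)
    if t.size < 3:
        return []
    isis = np.diff(t)
    mean_isi = isis.mean()
    span = t[-1] - t[0]
    r = rate if rate is not None else t.size / span
    seeds = np.flatnonzero(isis < p * mean_isi)
    raw: List[Tuple[int, int]] = []
    for k in seeds:
        if raw and k <= raw[-1][1]:
            continue  # already inside the previous burst
        i, j = k, k + 1
        s = _set_surprise(t, i, j, r)
        while j + 1 < t.size:
            s_ext = _set_surprise(t, i, j + 1, r)
            if s_ext <= s:
                break
            j, s = j + 1, s_ext
        while j - i >= 1:
            s_pr = _set_surprise(t, i + 1, j, r)
            if s_pr <= s:
                break
            i, s = i + 1, s_pr
        if j - i + 1 >= 3:
            raw.append((i, j))
    # merge overlapping or adjacent index ranges
    merged: List[Tuple[int, int]] = []
    for i, j in raw:
        if merged and i <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], j))
        else:
            merged.append((i, j))
    return [
        Burst(
            start_index=i,
            end_index=j,
            start_time=t[i],
            end_time=t[j],
            n_spikes=j - i + 1,
            surprise=_set_surprise(t, i, j, r),
        )
        for i, j in merged
    ]


@dataclass
class BurstFeatures:
    within_burst_max_freq: float = 0.0  # Hz, 1 / shortest within-burst ISI
    within_burst_n_spikes: float = 0.0  # mean spikes per burst
    pct_burst_spikes: float = 0.0  # % of all spikes inside bursts
    burst_freq: float = 0.0  # bursts per second
    mean_surprise: float = 0.0
    max_surprise: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])


def burst_features(spike_times, segment_duration_s: float = 5.0, p: float = 0.2) -> BurstFeatures:
    """Six Poisson-Surprise burst features of a spontaneous segment;
    all-zero when no bursts (or no spikes) are found."""
    t = np.asarray(spike_times, dtype=np.float64)
    if t.size == 0:
        logger.warning("empty spike train; burst features set to zero")
        return BurstFeatures()
    bursts = detect_bursts(t, p=p)
    if not bursts:
        return BurstFeatures()
    min_isis = [np.diff(t[b.start_index : b.end_index + 1]).min() for b in bursts]
    n_burst_spikes = sum(b.n_spikes for b in bursts)
    surprises = [b.surprise for b in bursts]
    return BurstFeatures(
        within_burst_max_freq=float(1.0 / np.min(min_isis)),
        within_burst_n_spikes=float(np.mean([b.n_spikes for b in bursts])),
        pct_burst_spikes=100.0 * n_burst_spikes / t.size,
        burst_freq=len(bursts) / segment_duration_s,
        mean_surprise=float(np.mean(surprises)),
        max_surprise=float(np.max(surprises)),
    )


def spontaneous_segment(
    rec: EnsembleRecording, unit: str, min_duration_s: float = 5.0
) -> Tuple[np.ndarray, float]:
    """Concatenate the pre-onset epochs of a unit into one continuous
    spontaneous segment (times rebased); stops once ``min_duration_s`` is
    accumulated.  Returns (spike times, total duration)."""
    times: List[np.ndarray] = []
    offset = 0.0
    epoch = rec.stim_onset_s
    for sid in rec.stimulus_ids:
        for tr in range(rec.trials_per_stimulus):
            t = rec.get_spikes(unit, sid, tr)
            times.append(t[t < epoch] + offset)
            offset += epoch
            if offset >= min_duration_s:
                return np.concatenate(times), offset
    return np.concatenate(times) if times else np.empty(0), offset


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------


@dataclass
class NeuronTypeModel:
    classifier: LogisticRegression
    train_min: np.ndarray
    train_max: np.ndarray
    classes: Tuple[str, str] = ("LN", "PN")
    separate_test_scaler: bool = True
    feature_names: Tuple[str, ...] = FEATURE_NAMES


def _minmax(X: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    rng = hi - lo
    const = rng <= 0
    if const.any():
        logger.warning("constant feature column(s) %s scaled to 0.5", np.flatnonzero(const))
    out = np.empty_like(X, dtype=np.float64)
    out[:, const] = 0.5
    safe = ~const
    out[:, safe] = (X[:, safe] - lo[safe]) / rng[safe]
    return out


def _to_matrix(features: Sequence) -> np.ndarray:
    rows = [f.as_array() if isinstance(f, BurstFeatures) else np.asarray(f, float) for f in features]
    return np.vstack(rows)


def fit_type_classifier(
    features: Sequence,
    labels: Sequence[str],
    separate_test_scaler: bool = True,
) -> NeuronTypeModel:
    """Min-max scale the training features to [0, 1] and fit a logistic
    regression of PN vs LN."""
    X = _to_matrix(features)
    y = np.asarray(labels)
    if len(set(y)) != 2:
        raise ValueError("training labels must contain both classes")
    lo, hi = X.min(axis=0), X.max(axis=0)
    clf = LogisticRegression(max_iter=1000)
    clf.fit(_minmax(X, lo, hi), y)
    return NeuronTypeModel(
        classifier=clf,
        train_min=lo,
        train_max=hi,
        classes=tuple(sorted(set(y))),
        separate_test_scaler=separate_test_scaler,
    )


def classify(model: NeuronTypeModel, features: Sequence) -> List[Tuple[str, float]]:
    """Predict (type, probability-of-predicted-type) per unit.  With
    ``separate_test_scaler`` the test features are min-max scaled with
    their own bounds, mirroring the original two-scaler procedure."""
    X = _to_matrix(features)
    if model.separate_test_scaler and X.shape[0] > 1:
        Xs = _minmax(X, X.min(axis=0), X.max(axis=0))
    else:
        Xs = _minmax(X, model.train_min, model.train_max)
    probs = model.classifier.predict_proba(Xs)
    preds = model.classifier.predict(Xs)
    out = []
    for pred, prob in zip(preds, probs):
        k = list(model.classifier.classes_).index(pred)
        out.append((str(pred), float(prob[k])))
    return out
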