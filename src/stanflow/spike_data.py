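"""Domain types and I/O for population spike-train recordings.

An :class:`EnsembleRecording` holds the spike times of a population of
simultaneously recorded units across a panel of stimuli, each presented
for a fixed number of trials.  Spike times are stored in seconds relative
to trial start; milliseconds appear only in user-facing parameters
(bin widths, history-window lengths).

The module also provides the discretization steps feeding the attention
encoder: binning a trial into an ``N x T`` count matrix, extracting the
``N x Delta`` history window that ends at a given spike, and converting a
spike series into its interspike-interval (ISI) sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "EnsembleRecording",
    "BinnedSpikeArray",
    "BinnedWindow",
    "ISISequence",
    "load_recording",
    "write_recording",
    "bin_spikes",
    "window_history",
    "extract_isis",
]

STIMULUS_CLASSES = ("behavioral", "non_behavioral", "control")


class RecordingFormatError(ValueError):
    """Raised for malformed recording files (missing keys, bad schema)."""


class RecordingValidationError(ValueError):
    """Raised when spike data violate the recording invariants."""


@dataclass
class EnsembleRecording:
    """Population spike trains for one ensemble.

    ``spikes`` maps ``(unit_id, stimulus_id, trial)`` to a strictly
    increasing array of spike times in seconds within ``[0,
    trial_duration_s]``.  Series with no spikes may simply be absent.
    """

    unit_ids: List[str]
    stimuli: List[Tuple[str, str]]  # (stimulus_id, class label)
    trials_per_stimulus: int
    spikes: Dict[Tuple[str, str, int], np.ndarray]
    stim_onset_s: float
    stim_duration_s: float = 0.400
    trial_duration_s: float = 3.0

    def __post_init__(self):
        self.spikes = {k: np.asarray(v, dtype=np.float64) for k, v in self.spikes.items()}
        self.validate()

    # -- lookup helpers ---------------------------------------------------
    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_stimuli(self) -> int:
        return len(self.stimuli)

    @property
    def stimulus_ids(self) -> List[str]:
        return [s for s, _ in self.stimuli]

    @property
    def stimulus_classes(self) -> Dict[str, str]:
        return dict(self.stimuli)

    def unit_index(self, unit_id: str) -> int:
        return self.unit_ids.index(unit_id)

    def stimulus_index(self, stimulus_id: str) -> int:
        return self.stimulus_ids.index(stimulus_id)

    def get_spikes(self, unit_id: str, stimulus_id: str, trial: int) -> np.ndarray:
        if unit_id not in self.unit_ids:
            raise KeyError(f"unknown unit {unit_id!r}")
        if stimulus_id not in self.stimulus_ids:
            raise KeyError(f"unknown stimulus {stimulus_id!r}")
        if not 0 <= trial < self.trials_per_stimulus:
            raise KeyError(f"trial {trial} outside 0..{self.trials_per_stimulus - 1}")
        return self.spikes.get((unit_id, stimulus_id, trial), np.empty(0))

    def validate(self) -> None:
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise RecordingValidationError("duplicate unit identifiers")
        if len(set(self.stimulus_ids)) != len(self.stimulus_ids):
            raise RecordingValidationError("duplicate stimulus identifiers")
        for sid, cls in self.stimuli:
            if cls not in STIMULUS_CLASSES:
                raise RecordingValidationError(f"stimulus {sid!r} has unknown class {cls!r}")
        for (u, s, tr), times in self.spikes.items():
            if u not in self.unit_ids:
                raise RecordingValidationError(f"spikes reference unknown unit {u!r}")
            if s not in self.stimulus_ids:
                raise RecordingValidationError(f"spikes reference unknown stimulus {s!r}")
            if not 0 <= tr < self.trials_per_stimulus:
                raise RecordingValidationError(
                    f"trial index {tr} for ({u}, {s}) outside 0..{self.trials_per_stimulus - 1}"
                )
            if times.size and (np.any(times < 0) or np.any(times > self.trial_duration_s)):
                raise RecordingValidationError(
                    f"spike time outside [0, {self.trial_duration_s}] s in ({u}, {s}, {tr})"
                )
            if times.size > 1 and np.any(np.diff(times) <= 0):
                raise RecordingValidationError(
                    f"non-increasing spike times in ({u}, {s}, {tr})"
                )


@dataclass
class BinnedSpikeArray:
    """``N x T`` spike-count matrix for one (stimulus, trial)."""

    counts: np.ndarray
    bin_ms: float
    t0_s: float = 0.0

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def bin_s(self) -> float:
        return self.bin_ms / 1000.0

    @property
    def span_s(self) -> float:
        return self.n_bins * self.bin_s


@dataclass
class BinnedWindow:
    """``N x Delta`` history window ending at the bin containing a spike."""

    window: np.ndarray
    target_unit: int
    last_spike_time: float
    delta_ms: float


@dataclass
class ISISequence:
    unit: str
    stimulus: str
    trial: int
    isis: np.ndarray = field(default_factory=lambda: np.empty(0))
    last_spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))


# ---------------------------------------------------------------------------
# I/O: events CSV + metadata JSON, or a single HDF5 container
# ---------------------------------------------------------------------------

_META_KEYS = (
    "unit_ids",
    "stimuli",
    "trials_per_stimulus",
    "stim_onset_s",
    "stim_duration_s",
    "trial_duration_s",
)


def write_recording(rec: EnsembleRecording, path) -> None:
    """Write a recording to ``path`` (a directory -> events.csv + metadata.json,
    or a ``.h5`` file)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        _write_hdf5(rec, path)
        return
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for (u, s, tr), times in sorted(rec.spikes.items()):
        for t in times:
            rows.append((u, s, tr, t))
    df = pd.DataFrame(rows, columns=["unit_id", "stimulus_id", "trial", "spike_time_s"])
    df.to_csv(path / "events.csv", index=False, float_format="%.9f")
    meta = {
        "unit_ids": rec.unit_ids,
        "stimuli": dict(rec.stimuli),
        "trials_per_stimulus": rec.trials_per_stimulus,
        "stim_onset_s": rec.stim_onset_s,
        "stim_duration_s": rec.stim_duration_s,
        "trial_duration_s": rec.trial_duration_s,
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=2))


def load_recording(path) -> EnsembleRecording:
    """Load a recording written by :func:`write_recording`."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _read_hdf5(path)
    meta_path = path / "metadata.json"
    events_path = path / "events.csv"
    if not meta_path.exists() or not events_path.exists():
        raise RecordingFormatError(f"{path} must contain events.csv and metadata.json")
    meta = json.loads(meta_path.read_text())
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise RecordingFormatError(f"metadata.json missing keys: {missing}")
    df = pd.read_csv(events_path)
    expected_cols = ["unit_id", "stimulus_id", "trial", "spike_time_s"]
    if list(df.columns) != expected_cols:
        raise RecordingFormatError(f"events.csv header must be {expected_cols}")
    dup = df.duplicated(subset=expected_cols, keep=False)
    if dup.any():
        offenders = df[dup].to_dict("records")[:10]
        raise RecordingValidationError(f"duplicate event rows: {offenders}")
    spikes: Dict[Tuple[str, str, int], np.ndarray] = {}
    for (u, s, tr), grp in df.groupby(["unit_id", "stimulus_id", "trial"], sort=False):
        times = grp["spike_time_s"].to_numpy(dtype=np.float64)
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise RecordingValidationError(
                f"non-increasing spike times within series ({u}, {s}, {tr})"
            )
        spikes[(str(u), str(s), int(tr))] = times
    return EnsembleRecording(
        unit_ids=[str(u) for u in meta["unit_ids"]],
        stimuli=[(str(k), str(v)) for k, v in meta["stimuli"].items()],
        trials_per_stimulus=int(meta["trials_per_stimulus"]),
        spikes=spikes,
        stim_onset_s=float(meta["stim_onset_s"]),
        stim_duration_s=float(meta["stim_duration_s"]),
        trial_duration_s=float(meta["trial_duration_s"]),
    )


def _write_hdf5(rec: EnsembleRecording, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["unit_ids"] = json.dumps(rec.unit_ids)
        f.attrs["stimuli"] = json.dumps(dict(rec.stimuli))
        f.attrs["trials_per_stimulus"] = rec.trials_per_stimulus
        f.attrs["stim_onset_s"] = rec.stim_onset_s
        f.attrs["stim_duration_s"] = rec.stim_duration_s
        f.attrs["trial_duration_s"] = rec.trial_duration_s
        g = f.create_group("spikes")
        for (u, s, tr), times in rec.spikes.items():
            g.create_dataset(f"{u}/{s}/{tr}", data=times)


def _read_hdf5(path: Path) -> EnsembleRecording:
    import h5py

    with h5py.File(path, "r") as f:
        for key in ("unit_ids", "stimuli", "trials_per_stimulus"):
            if key not in f.attrs:
                raise RecordingFormatError(f"HDF5 container missing attribute {key!r}")
        spikes = {}
        g = f["spikes"]
        for u in g:
            for s in g[u]:
                for tr in g[u][s]:
                    spikes[(u, s, int(tr))] = g[u][s][tr][...]
        return EnsembleRecording(
            unit_ids=json.loads(f.attrs["unit_ids"]),
            stimuli=list(json.loads(f.attrs["stimuli"]).items()),
            trials_per_stimulus=int(f.attrs["trials_per_stimulus"]),
            spikes=spikes,
            stim_onset_s=float(f.attrs["stim_onset_s"]),
            stim_duration_s=float(f.attrs["stim_duration_s"]),
            trial_duration_s=float(f.attrs["trial_duration_s"]),
        )


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------


def bin_spikes(rec: EnsembleRecording, stimulus: str, trial: int, bin_ms: float = 1.0) -> BinnedSpikeArray:
    """Bin one trial into an ``N x T`` count matrix.

    Bins are half-open ``[left, right)`` except the final bin, which is
    closed on the right (a spike exactly at ``trial_duration_s`` lands in
    the last bin).
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    if stimulus not in rec.stimulus_ids:
        raise KeyError(f"unknown stimulus {stimulus!r}")
    if not 0 <= trial < rec.trials_per_stimulus:
        raise KeyError(f"unknown trial {trial}")
    bin_s = bin_ms / 1000.0
    n_bins = int(np.ceil(rec.trial_duration_s / bin_s - 1e-9))
    edges = np.arange(n_bins + 1) * bin_s
    edges[-1] = max(edges[-1], rec.trial_duration_s)
    counts = np.zeros((rec.n_units, n_bins), dtype=np.int64)
    for i, u in enumerate(rec.unit_ids):
        times = rec.get_spikes(u, stimulus, trial)
        if times.size:
            counts[i], _ = np.histogram(times, bins=edges)
    return BinnedSpikeArray(counts=counts, bin_ms=bin_ms, t0_s=0.0)


def window_history(
    binned: BinnedSpikeArray, target_unit: int, last_spike_time: float, delta_ms: float
) -> BinnedWindow:
    """Extract the ``Delta``-long history window whose right edge is the bin
    containing ``last_spike_time``; zero-pad on the left before recording
    start."""
    w = delta_ms / binned.bin_ms
    if delta_ms <= 0 or abs(w - round(w)) > 1e-9:
        raise ValueError("delta_ms must be a positive multiple of bin_ms")
    w = int(round(w))
    t_rel = last_spike_time - binned.t0_s
    if t_rel < 0 or t_rel > binned.span_s + 1e-12:
        raise ValueError(
            f"last_spike_time {last_spike_time} outside binned span "
            f"[{binned.t0_s}, {binned.t0_s + binned.span_s}]"
        )
    j = min(int(t_rel / binned.bin_s), binned.n_bins - 1)
    n = binned.counts.shape[0]
    window = np.zeros((n, w), dtype=np.float64)
    lo = j - w + 1
    src_lo = max(lo, 0)
    window[:, src_lo - lo :] = binned.counts[:, src_lo : j + 1]
    return BinnedWindow(window=window, target_unit=target_unit, last_spike_time=last_spike_time, delta_ms=delta_ms)


def extract_isis(rec: EnsembleRecording, unit: str, stimulus: str, trial: int) -> ISISequence:
    """Interspike intervals of one series; fewer than 2 spikes yields an
    empty sequence."""
    times = rec.get_spikes(unit, stimulus, trial)
    if times.size < 2:
        return ISISequence(unit=unit, stimulus=stimulus, trial=trial)
    return ISISequence(
        unit=unit,
        stimulus=stimulus,
        trial=trial,
        isis=np.diff(times),
        last_spike_times=times[:-1].copy(),
    )
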