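"""Synthetic population spike-train simulator with planted ground truth.

Emulates the structure of small insect antennal-lobe ensemble recordings:
a handful of units (7-19), a stimulus panel split into behavioral /
non-behavioral / control classes, five trials per stimulus, a 400 ms
stimulation window inside each trial, baseline and evoked firing, planted
synchronized subsets, and two spontaneous-dynamics phenotypes (bursty
PN-like units vs regular LN-like units).

Synchrony is planted by mother-process thinning (common input): each sync
group shares a mother renewal train during stimuli of its assigned class
and each member keeps every mother spike with probability ``sync_copy_prob``
plus Gaussian jitter, superposed on its own background.  This produces a
central cross-correlogram peak at lag 0 (within the jitter) for same-group
pairs that the synchronization metrics downstream must detect.  The mother
train is a regular gamma renewal by default (``sync_mother_shape`` > 1):
a memoryless (Poisson) common input would make group members coincide
without their histories carrying any information about each other's next
spike, leaving nothing for history-based models to attend to; a regular
common rhythm is both closer to odor-evoked synchronous volleys and
actually predictive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np

from .spike_data import EnsembleRecording

__all__ = [
    "SimulationConfig",
    "simulate_population",
    "planted_truth",
    "default_benchmark_config",
    "typing_benchmark_config",
]

PN_LIKE = "PN_like"
LN_LIKE = "LN_like"


@dataclass
class SimulationConfig:
    n_units: int
    unit_types: List[str]  # PN_like / LN_like per unit
    group_assignments: Dict[int, Optional[str]]  # unit index -> sync group id or None
    group_stimulus_class: Dict[str, str]  # sync group id -> stimulus class it follows
    stimuli: List[Tuple[str, str]]  # (stimulus id, class)
    trials_per_stimulus: int = 5
    trial_duration_s: float = 3.0
    stim_onset_s: float = 1.0
    stim_duration_s: float = 0.4
    baseline_rate_hz: float = 5.0
    evoked_rate_hz: Dict[Tuple[int, str], float] = field(default_factory=dict)
    sync_mother_rate_hz: float = 28.6
    sync_mother_shape: float = 6.0  # gamma shape of the mother renewal (1 = Poisson)
    sync_copy_prob: float = 0.7
    sync_jitter_ms: float = 2.0
    burst_intra_rate_hz: float = 100.0
    burst_mean_spikes: float = 4.0
    interburst_rate_hz: float = 2.0
    gamma_shape: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if len(self.unit_types) != self.n_units:
            raise ValueError("unit_types must have one entry per unit")
        if not 0.0 <= self.sync_copy_prob <= 1.0:
            raise ValueError("sync_copy_prob must lie in [0, 1]")
        rates = [self.baseline_rate_hz, self.sync_mother_rate_hz, *self.evoked_rate_hz.values()]
        if any(r < 0 for r in rates):
            raise ValueError("rates must be nonnegative")

    @property
    def unit_ids(self) -> List[str]:
        return [f"u{i:02d}" for i in range(self.n_units)]

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["group_assignments"] = {str(k): v for k, v in self.group_assignments.items()}
        d["evoked_rate_hz"] = {f"{u}|{s}": r for (u, s), r in self.evoked_rate_hz.items()}
        d["stimuli"] = [list(p) for p in self.stimuli]
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["group_assignments"] = {int(k): v for k, v in d["group_assignments"].items()}
        d["evoked_rate_hz"] = {
            (int(k.split("|")[0]), k.split("|")[1]): v for k, v in d["evoked_rate_hz"].items()
        }
        d["stimuli"] = [tuple(p) for p in d["stimuli"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# Elementary renewal processes
# ---------------------------------------------------------------------------


def _poisson_train(rate: float, t0: float, t1: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0 or t1 <= t0:
        return np.empty(0)
    # draw a comfortable surplus of exponential gaps, then truncate
    n_guess = max(16, int(rate * (t1 - t0) * 2 + 10 * np.sqrt(rate * (t1 - t0) + 1)))
    t = t0 + np.cumsum(rng.exponential(1.0 / rate, size=n_guess))
    while t.size and t[-1] < t1:
        t = np.concatenate([t, t[-1] + np.cumsum(rng.exponential(1.0 / rate, size=n_guess))])
    return t[t < t1]


def _gamma_train(rate: float, shape: float, t0: float, t1: float, rng: np.random.Generator) -> np.ndarray:
    """Gamma-renewal train with mean rate ``rate`` and shape ``shape``
    (shape > 1 yields regular, low-CV firing)."""
    if rate <= 0 or t1 <= t0:
        return np.empty(0)
    scale = 1.0 / (rate * shape)
    out, t = [], t0 + rng.gamma(shape, scale)
    while t < t1:
        out.append(t)
        t += rng.gamma(shape, scale)
    return np.asarray(out)


def _burst_train(
    intra_rate: float,
    mean_spikes: float,
    interburst_rate: float,
    t0: float,
    t1: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Alternating-renewal burst process: quiescent gaps Exp(interburst_rate),
    bursts of geometric length (mean ``mean_spikes``) at Exp(intra_rate) ISIs."""
    out, t = [], t0
    p_geom = 1.0 / mean_spikes
    while True:
        t += rng.exponential(1.0 / interburst_rate)
        if t >= t1:
            break
        n = rng.geometric(p_geom)
        for _ in range(n):
            if t >= t1:
                break
            out.append(t)
            t += rng.exponential(1.0 / intra_rate)
    return np.asarray(out)


def _clean(times: np.ndarray, t1: float) -> np.ndarray:
    """Sort, clip to [0, t1] and enforce strictly increasing times."""
    times = np.sort(times[(times >= 0) & (times <= t1)])
    if times.size < 2:
        return times
    keep = np.concatenate([[True], np.diff(times) > 1e-9])
    return times[keep]


# ---------------------------------------------------------------------------
# Population simulation
# ---------------------------------------------------------------------------


def simulate_population(config: SimulationConfig) -> EnsembleRecording:
    """Simulate one ensemble recording under ``config``.

    Background activity runs over the whole trial (bursty for PN-like
    units, regular gamma-renewal for LN-like units).  Units with a private
    evoked rate for a stimulus have their background replaced by a Poisson
    train at that rate inside the stimulation window.  Sync-group members
    additionally receive thinned, jittered copies of a shared mother train
    during stimuli of the group's class.
    """
    if not config.stimuli:
        raise ValueError("config must define at least one stimulus")
    onset, dur = config.stim_onset_s, config.stim_duration_s
    t_end = config.trial_duration_s
    jitter_s = config.sync_jitter_ms / 1000.0
    groups = sorted({g for g in config.group_assignments.values() if g is not None})
    spikes: Dict[Tuple[str, str, int], np.ndarray] = {}

    for q_idx, (sid, cls) in enumerate(config.stimuli):
        for trial in range(config.trials_per_stimulus):
            # shared mother trains for groups whose class matches this stimulus
            mothers = {}
            for g in groups:
                if config.group_stimulus_class.get(g) == cls:
                    rng_m = np.random.default_rng([config.seed, 7919, q_idx, trial, groups.index(g)])
                    mothers[g] = _gamma_train(
                        config.sync_mother_rate_hz, config.sync_mother_shape, onset, onset + dur, rng_m
                    )
            for u in range(config.n_units):
                rng = np.random.default_rng([config.seed, q_idx, trial, u])
                if config.unit_types[u] == PN_LIKE:
                    bg = _burst_train(
                        config.burst_intra_rate_hz,
                        config.burst_mean_spikes,
                        config.interburst_rate_hz,
                        0.0,
                        t_end,
                        rng,
                    )
                else:
                    bg = _gamma_train(config.baseline_rate_hz, config.gamma_shape, 0.0, t_end, rng)
                parts = [bg]
                evoked = config.evoked_rate_hz.get((u, sid), 0.0)
                if evoked > 0:
                    parts[0] = bg[(bg < onset) | (bg >= onset + dur)]
                    parts.append(_poisson_train(evoked, onset, onset + dur, rng))
                g = config.group_assignments.get(u)
                if g is not None and g in mothers:
                    mother = mothers[g]
                    keep = rng.random(mother.size) < config.sync_copy_prob
                    copied = mother[keep]
                    if jitter_s > 0 and copied.size:
                        copied = copied + rng.normal(0.0, jitter_s, size=copied.size)
                    parts.append(copied)
                times = _clean(np.concatenate(parts), t_end)
                if times.size:
                    spikes[(config.unit_ids[u], sid, trial)] = times

    return EnsembleRecording(
        unit_ids=config.unit_ids,
        stimuli=list(config.stimuli),
        trials_per_stimulus=config.trials_per_stimulus,
        spikes=spikes,
        stim_onset_s=onset,
        stim_duration_s=dur,
        trial_duration_s=t_end,
    )


def planted_truth(config: SimulationConfig) -> dict:
    """Ground-truth labels for downstream oracles: stimulus -> class,
    unit -> sync group (units in no group are omitted), unit -> type."""
    return {
        "stimulus_classes": {sid: cls for sid, cls in config.stimuli},
        "sync_groups": {
            config.unit_ids[u]: g for u, g in config.group_assignments.items() if g is not None
        },
        "unit_types": {config.unit_ids[u]: config.unit_types[u] for u in range(config.n_units)},
    }


def default_benchmark_config(seed: int = 0) -> SimulationConfig:
    """The 12-unit benchmark ensemble used throughout the test suite.

    Units 0-5 form one sync group driven by the behavioral stimuli; units
    6-11 are independent background units with no evoked drive.  Half of
    each subset is PN-like, half LN-like.  The class signal is the
    presence of the synchronized ensemble response: behavioral stimuli
    recruit the sync group to ~25 Hz through the thinned mother train
    (baseline + p_sync * mother), while non-behavioral stimuli — like the
    control — recruit nobody, so the independent units are genuinely
    uninformative about the stimulus class and the planted group carries
    the whole discriminative burden.
    """
    n = 12
    types = [PN_LIKE] * 3 + [LN_LIKE] * 3 + [PN_LIKE] * 3 + [LN_LIKE] * 3
    groups: Dict[int, Optional[str]] = {u: ("G1" if u < 6 else None) for u in range(n)}
    stimuli = [(f"B{i}", "behavioral") for i in range(1, 5)]
    stimuli += [(f"NB{i}", "non_behavioral") for i in range(1, 4)]
    stimuli += [("CTRL", "control")]
    evoked: Dict[Tuple[int, str], float] = {}
    p_sync = 0.7
    return SimulationConfig(
        n_units=n,
        unit_types=types,
        group_assignments=groups,
        group_stimulus_class={"G1": "behavioral"},
        stimuli=stimuli,
        baseline_rate_hz=5.0,
        evoked_rate_hz=evoked,
        sync_mother_rate_hz=(25.0 - 5.0) / p_sync,
        sync_copy_prob=p_sync,
        sync_jitter_ms=2.0,
        seed=seed,
    )


def typing_benchmark_config(seed: int = 0, n_pn: int = 20, n_ln: int = 20) -> SimulationConfig:
    """Spontaneous-only ensemble for the PN/LN classifier benchmark: no
    evoked drive, two 2.5 s pre-onset epochs per unit give 5 s of
    spontaneous activity."""
    n = n_pn + n_ln
    return SimulationConfig(
        n_units=n,
        unit_types=[PN_LIKE] * n_pn + [LN_LIKE] * n_ln,
        group_assignments={u: None for u in range(n)},
        group_stimulus_class={},
        stimuli=[("CTRL", "control")],
        trials_per_stimulus=2,
        trial_duration_s=2.5,
        stim_onset_s=2.5,
        stim_duration_s=0.0,
        baseline_rate_hz=8.0,
        seed=seed,
    )
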