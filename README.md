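# stanflow

Generative modeling of population spike trains with spatial-temporal
attention and a conditional normalizing flow, plus the synchronization
and cell-typing analyses built on top of it. The package targets small
simultaneously recorded ensembles — the motivating system is the insect
antennal lobe, where projection neurons (PNs) and local interneurons
(LNs) synchronize selectively in response to behaviorally meaningful
odor blends — but nothing in the code is specific to olfaction.

## The model

Spiking of each unit *n* is treated as a point process over interspike
intervals (ISIs). Given the population history window
S<sub>i−1[Δ]</sub> ∈ ℝ<sup>N×Δ</sup> ending at the previous spike, the
stimulus q and the previous spike time t<sub>i−1</sub>, the model learns

&nbsp;&nbsp;&nbsp;&nbsp;P(τ<sub>i</sub> | S<sub>i−1[Δ]</sub>, q, t<sub>i−1</sub>)

as the composition of

1. **a spatial-temporal attention encoder** — an LSTM summarizes the
   window into temporal weights α ∈ ℝ<sup>Δ</sup> (softmax) and, through
   per-unit embeddings, spatial weights β ∈ ℝ<sup>N</sup> (**sparsemax**,
   the simplex projection, so uninformative units get exactly zero
   weight); the window reweighted by the mean-normalized βα<sup>T</sup>
   is encoded into a context vector;
2. **a conditional normalizing flow** — monotone context-conditioned
   transforms of log-ISI with exact likelihoods (the scalar target makes
   the Jacobian log-determinant a plain sum) and exact sampling by
   inversion.

Each unit's model is trained by maximum likelihood with a
trial-rotation cross-validation (train 3 / validate 1 / test 1).
Averaging β over spikes, units, and rotations yields a Q×N
**synchronization summary matrix B**; its rows are clustered
(t-SNE + 2-means) against the behavioral/non-behavioral stimulus
annotation, compared with two classic pairwise baselines — the
shift-predictor-corrected cross-correlogram index (**ESI**, δ = 5 ms,
T = 1 s) and the kernelized binless cosine similarity (**KB**,
ϕ = 5 ms) — and probed by unit ablation. A separate module detects
bursts with the Poisson-Surprise criterion and classifies units into
PN-like vs LN-like from six burst features. A bundled simulator plants
ground-truth synchrony (common-input thinning), stimulus classes, and
both spontaneous phenotypes so every stage can be tested against known
truth. See `docs/methods.md` for the full model description and design
rationale.

## Worked example

```python
import numpy as np
from scipy import stats
from stanflow.synthetic_data import default_benchmark_config, simulate_population
from stanflow.training import TrainConfig, make_splits, train_neuron_model, generate_spike_train
from stanflow.sync_metrics import esi
from stanflow.neuron_typing import burst_features, spontaneous_segment

rec = simulate_population(default_benchmark_config(seed=1))

# pairwise synchrony under a behavioral stimulus: planted pair vs independents
t0, t1 = rec.stim_onset_s, rec.stim_onset_s + 1.0
def win(u, tr):
    t = rec.get_spikes(u, "B1", tr)
    return t[(t >= t0) & (t < t1)]
si_sync = esi(win("u00", 0), win("u01", 0), [win("u01", k) for k in range(1, 5)])
si_ind  = esi(win("u06", 0), win("u07", 0), [win("u07", k) for k in range(1, 5)])

# train one neuron model and roll out a spike train on the held-out trial
model = train_neuron_model(rec, "u03", make_splits(5)[0], TrainConfig(epochs=30, seed=0))
gen = generate_spike_train(model, rec, "B1", seed=0)
emp = rec.get_spikes("u03", "B1", model.split.test_trial)
ks = stats.ks_2samp(np.diff(gen), np.diff(emp))
```

Output (printed by `rec` sizes and the quantities above):

```
12 units, 8 stimuli, 10099 spikes
ESI u00-u01 (same group): 4.6%   u06-u07 (independent): 0.0%
u03 best validation NLL: -1.152
generated 20 spikes vs 22 empirical on the held-out trial
ISI two-sample KS: 0.185 (p = 0.79)
u00: 75% burst spikes, 1.00 bursts/s, max surprise 16.0
u03: 0% burst spikes, 0.00 bursts/s, max surprise 0.0
```

Reading it: the planted same-group pair shows a clear excess of
±2.5 ms coincidences over its shift predictor (4.6%) while the
independent pair sits at chance (0.0%); the trained model's rollout
matches the held-out trial in spike count and ISI distribution (small
KS statistic, p ≈ 1); and the burst features separate the bursty
PN-like unit u00 (75% of spontaneous spikes inside Poisson-Surprise
bursts) from the regular LN-like unit u03 (none).

A command-line interface mirrors the library:

```bash
stanflow simulate --out data/ --seed 7
stanflow train --data data/ --unit u03 --rotation 0 --out models/
stanflow sync --data data/ --method esi --out sync.json
stanflow cluster --sync sync.json --data data/ --seeds 10
stanflow classify-neurons --data data/ --train-labels labels.csv --out types.csv
```

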