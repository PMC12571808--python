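# Methods

`stanflow` models each neuron of a simultaneously recorded population as a
conditional point process: the interspike interval (ISI) of unit *n*
following a spike at time *t*<sub>i−1</sub> is modeled as

P(τ<sub>i</sub> | S<sub>i−1[Δ]</sub>, q, t<sub>i−1</sub>),

where S<sub>i−1[Δ]</sub> is the N×Δ binned history of the whole population
in a Δ-long window ending at the previous spike, and q is the stimulus
identity. The model has two parts: a spatial-temporal attention encoder
that compresses the population window into a context vector while
exposing interpretable attention weights, and a conditional normalizing
flow that turns the context into an exact ISI density. The spatial
weights, averaged over spikes and units, form a stimulus-by-unit
synchronization summary matrix B whose rows are compared, clustered, and
ablated; classic pairwise indices (shift-corrected cross-correlogram ESI,
kernelized binless similarity) serve as baselines, and a Poisson-Surprise
burst analysis classifies units into bursty (PN-like) and regular
(LN-like) types.

## Discretization

Spike times are kept in seconds; user-facing widths are in milliseconds.
Trials are binned at 1 ms (counts, not binary, by default — a `binarize`
flag exists); bins are half-open `[left, right)` with the final bin
closed. The history window is Δ = 20 ms by default (Δ = 5 ms remains
usable, and the window sweep is part of the evaluation); it ends at the
bin containing t<sub>i−1</sub>, inclusive, and is zero-padded before
recording start. The first ISI of a trial conditions on t<sub>i−1</sub> =
the first spike; generation starts from trial onset with an empty
history.

## Attention encoder

Two single-layer LSTMs (hidden size 32) and three small affine heads:

* `f1` scans the window along time (inputs are length-N population bin
  vectors); its final hidden state drives temporal weights
  α = softmax(tanh(W<sub>α</sub>h + b<sub>α</sub>)) ∈ ℝ<sup>Δ</sup>.
* A shared affine map embeds each unit's Δ-long row into d = 8
  dimensions; per unit the scalar logit tanh(W<sub>β</sub>[h*; e<sup>m</sup>; q] + b<sub>β</sub>)
  is computed with one weight vector shared across units, and
  **sparsemax** across units produces spatial weights β on the simplex
  with exact zeros. Sparsemax is the Euclidean projection onto the
  simplex (sort-threshold algorithm), verified against a KKT enumeration
  oracle. Because the logit map is shared, a constant shift (e.g. from
  the stimulus one-hot) moves all logits together and cannot by itself
  distinguish units; differentiation must come from the data.
* The window is reweighted elementwise by the mean-normalized outer
  product βα<sup>T</sup> — exactly multiplication by NΔ, since both
  weight vectors sum to one — and `f2` encodes the reweighted window into
  the context h′.

All gradients flow end-to-end (finite-difference checked at 1e-4); α and
β are computed quantities and remain on the simplex under any parameter
update.

### Two-timescale optimization

The attention heads (embedding, temporal, spatial) sit behind a long
saturating path — sparsemax ∘ tanh ∘ shared-affine — and receive weak,
diluted gradients compared to the LSTM/flow parameters, which can absorb
most of the likelihood gain on their own (the encoder sees the full
window whatever β is, so near-uniform β is a shallow plateau of the
loss). With a single learning rate the heads barely move within a
realistic epoch budget and the spatial weights stay uninformatively
uniform. The default optimizer therefore applies a 10× larger Adam step
to the head parameters (`TrainConfig.attention_lr_factor`); up to 200 epochs with early
stopping (patience 20).
This is the standard two-timescale remedy for attention heads that are
under-driven relative to their encoder.  The default batch size is 64
(about ten gradient steps per epoch per unit on the benchmark), base
learning rate 1e-3.

## Conditional flow

ISIs are mapped to the log scale, y = log(τ/τ<sub>ref</sub>) with
τ<sub>ref</sub> = 50 ms, which enforces positivity and contributes
−log τ to the log-Jacobian. Six context-conditioned monotone layers
follow:

y ↦ e<sup>s(x)</sup>·y + t(x) + Σ<sub>j</sub> γ<sub>j</sub>(x)·tanh(δ<sub>j</sub>(x)·(y − μ<sub>j</sub>(x))),

with γ<sub>j</sub>, δ<sub>j</sub> > 0 (exponential parameterizations,
clamped for stability; s clamped to [−5, 5]) so every layer is strictly
increasing in y. The scalar target makes the Jacobian trivially
triangular: the log-determinant is the exact sum of per-layer
log-derivatives. The base density is a standard Gaussian; conditioning
enters only through the transform. Parameters of each layer come from a
2-layer tanh MLP (width 64) reading the context
x = [h′; q; t<sub>i−1</sub>/T<sub>trial</sub>], with zero-initialized
output heads so the flow starts near the identity.

Design rationale: with purely affine layers conditioned on x alone the
flow collapses, for any fixed context, to a single affine map of log-ISI
— i.e. exactly a lognormal — and the best lognormal fit to a Gamma(2)
ISI law already has a population KS distance of 0.049, too coarse for
faithful ISI modeling. The saturating terms add the required shape
flexibility while keeping likelihoods exact and the inverse computable by
bisection (machine-precision round trips; `n_bumps=0` recovers the pure
affine/lognormal case used in closed-form tests). An augmented-variable
coupling pair was considered and rejected: its importance-sampled
marginal likelihood is no longer exactly normalized.

## Training protocol

One model per (unit, trial rotation). The five trials per stimulus
rotate cyclically: rotation r trains on {r, r+1, r+2}, validates on r+3,
tests on r+4; the checkpoint with the best validation NLL is kept and
the test trial is never touched during fitting. Each unit's model is
trained across all stimuli jointly (q is an input). Generation is an
autoregressive rollout teacher-forced on the held-out test trial: other
units' rows come from the recorded trial, the target's own row is updated
with generated spikes, and each step re-encodes the window at the last
generated spike.

## Synchronization summary and evaluation

Spatial weights are averaged over all spikes of a unit (every trial, by
default — the summary is an interpretability readout and averaging over
every spike minimizes its variance; the test trial still never enters
model fitting or selection, and a `val+test`-only readout is available),
per stimulus, then over rotations, then over units: B ∈ ℝ<sup>Q×N</sup>
with simplex rows (the average, not the sum, over spikes is used so
stimuli with different spike counts are comparable). Stimulus clustering reduces B's rows (or, for the pairwise
baselines, the upper-triangular vectorization of the per-stimulus ESI/KB
matrices) to 2-D with t-SNE (perplexity min(5, Q−1), 1000 iterations,
seeded), runs 2-means, and scores accuracy against the
behavioral/non-behavioral annotation under the best label permutation,
repeated over 10 seeded re-initializations (a reduced version of a
100-restart protocol). Accuracy on raw rows without t-SNE is reported as
a robustness column. Ablation recomputes the spatial weights with the removed units excluded
from the sparsemax competition: each spike's per-unit logits are cached
once (they do not depend on the other units), the removed entries are
dropped, and sparsemax is re-applied over the survivors before
re-averaging into B — the counterfactual in which the removed units were
never part of the ensemble. Plain column surgery on B (with or without
simplex re-projection) is kept as a fallback but cannot localize
attribution: rows of B are simplex vectors, so the complement of an
informative block is itself informative, and deleting provably
uninformative columns moves the features as much as deleting informative
ones.

ESI uses a ±50 ms, 1 ms-binned cross-correlogram over the 1000 ms
post-onset window; coincident events are spike pairs within ±δ/2 (δ =
5 ms) of zero lag; one trial is the raw pairing and the other four,
trial-shifted, form the shift predictor whose mean is subtracted; the
result is normalized by the two units' spike counts and expressed in
percent (identical trains ≈ 50%). KB convolves each train with the
causal exponential kernel exp(−t/ϕ)u(t), ϕ = 5 ms, on a 0.1 ms grid and
takes the cosine similarity (single spikes Δt apart give exp(−|Δt|/ϕ)
exactly); the same trial-shift correction is applied. The ESI
coincidence counter is tested against an O(n²) double loop, and the KB
grid against its closed form and grid refinement.

The per-unit response index is RI = ((r_odor − r_control) − r̄)/SD with
rates over 0–600 ms post-onset averaged across trials, and mean/SD taken
across stimuli. PSTHs use 20 ms bins, trial averaging, and a Gaussian
smoother (sd 3 bins, truncated at ±3 sd, reflected edges); z-scoring
subtracts the mean and divides by the SD of the **unsmoothed** 200 ms
pre-onset baseline — the SD of spontaneous activity. (Baseline statistics
on the smoothed trace are degenerate: ten 20 ms bins span barely one
smoothing window, and the resulting σ is an order of magnitude too
small.) The dissimilarity index is the Euclidean distance between a
reference row of B and each comparison row, normalized by the mean of
those distances.

## Neuron typing

Bursts are detected with the Poisson-Surprise criterion
S = rT − log Σ<sub>j≥n</sub>(rT)<sup>j</sup>/j!, computed through the
Poisson survival function (matches a 200-term series to 1e-9). Seeds are
successive spike pairs with ISI < p·mean ISI (p = 0.2); the rate r is the
segment's mean rate; sets grow forward one spike at a time while the
surprise strictly increases, are then pruned from the front under the
same rule, are kept if they hold ≥ 3 spikes, and overlapping sets merge.
(The original grow/prune order is under-specified; strict-increase greedy
is this package's declared variant.) Six features summarize 5 s of
spontaneous activity (concatenated pre-onset epochs): the maximum
within-burst instantaneous frequency, mean spikes per burst, percentage
of spikes in bursts, bursts per second, and the mean and maximum
surprise. A logistic regression on min-max-scaled features separates
PN-like from LN-like units; faithful to the original procedure, the test
set is scaled with its own min-max bounds (a flag restores conventional
train-bounds scaling).

## Synthetic benchmark

The simulator emulates small antennal-lobe ensemble recordings and gives
every downstream stage a planted ground truth. The default benchmark has
12 units — six in one synchronized group recruited to ≈25 Hz by the
behavioral stimuli, six independent background units with no evoked
drive — under 8 stimuli (4 behavioral, 3 non-behavioral, 1 control), 5
trials of 3 s, onset at 1 s, 400 ms stimulation, 5 Hz baseline. The
class signal is thus the presence of the synchronized ensemble response
itself: independent units are uninformative about stimulus class by
construction, which is what makes unit-ablation attribution
well-defined.
Background activity is an alternating-renewal burst process for PN-like
units (100 Hz intra-burst, geometric bursts of mean 4 spikes, 2 Hz
quiescent gaps; ISI CV > 1) and a gamma renewal (shape 6; CV < 1) for
LN-like units.

Synchrony is planted by mother-process thinning: during a stimulus of the
group's class, members keep each mother spike with probability
p<sub>sync</sub> = 0.7 and 2 ms Gaussian jitter (inside the 5 ms
coincidence window), superposed on their baseline background. The mother
train is a **regular gamma renewal (shape 6)** rather than a Poisson
train, a deliberate choice: a memoryless common input produces
coincidences whose timing is unpredictable from any history, so a
history-conditioned ISI model has provably nothing to attend to, while a
regular common rhythm — closer to the synchronous volleys seen in
odor-evoked activity — makes group members genuinely informative about
each other's next spike. Coincidence counters (ESI/KB) are indifferent
to this distinction. Mother rate is set so baseline + p·rate ≈ 25 Hz.

What the generator does not emulate: oscillatory LFP coupling, slow rate
drift, adaptation within the stimulation window, inhibitory (negative)
interactions, electrode artifacts, or spike-sorting errors. Passing the
planted-truth benchmarks therefore shows that the pipeline recovers
common-input group structure of the stated strength at these sample
sizes — not that it would resolve the weaker, messier synchrony of real
recordings.

## Problem sizes and numerical choices

The evaluation trains one model per (unit, rotation) for two of the five
trial rotations at 50 epochs and averages their summaries (12 units ≈
5 min on one core; a single rotation's summary is noticeably noisier —
at some seeds training-initialization noise alone flips one cluster
assignment); distribution-recovery checks use
5000 training ISIs and 2000-sample KS comparisons; clustering repeats 10
seeded restarts; the typing benchmark uses two independent cohorts of
20 + 20 units with 5 s of spontaneous activity each. Quadrature
normalization checks integrate on the log scale with adaptive quadrature
(tolerance 1e-3). Ties and degenerate cases are fixed conventions: KB of
an empty train is 0, ESI of an empty train is an error, a unit with no
spikes under a stimulus is skipped (with a warning) in the summary
average, constant feature columns scale to 0.5, and zero baseline
variance or zero rate-SD raise informative errors.

## Known limitations

* Per-neuron models scale linearly in ensemble size; no parameter
  sharing across units.
* The attention weights are a semi-interpretable byproduct of maximum
  likelihood: nothing forces them to be informative, and with a single
  learning rate they demonstrably stay at their uniform plateau; the
  two-timescale default is a remedy, not a guarantee.
* Closed-loop multi-unit generation (all units generated jointly) is out
  of scope; rollouts are teacher-forced on held-out context.
* The PN/LN classifier is validated on simulated phenotypes with
  well-separated burst statistics; real recordings are substantially
  harder.
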