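import numpy as np
import pytest

from stanflow.attention import AttentionParams
from stanflow.flow import FlowParams, ISIDensityModel
from stanflow.spike_data import EnsembleRecording
from stanflow.sync_metrics import (
    SyncSummary,
    attention_summary,
    cluster_stimuli,
    ablation_accuracy,
    dissimilarity_index,
    esi,
    kernelized_binless,
    pairwise_matrix,
    psth_zscore,
    response_index,
    upper_triangular_features,
)
from stanflow.training import CVSplit, TrainedNeuronModel


def brute_force_coincidences(t1, t2, half_width):
    """O(n^2) double-loop oracle for central-peak coincidence counting."""
    count = 0
    for a in t1:
        for b in t2:
            if abs(a - b) <= half_width:
                count += 1
    return count


class TestESI:
    def test_identical_trains_give_fifty_percent(self):
        # sparse identical trains, shuffles far away -> SI% = C/(2C) * 100
        t = np.arange(0.05, 1.0, 0.05)
        shuffles = [t + 0.013 + 0.002 * k for k in range(4)]  # no coincidences
        si = esi(t, t.copy(), shuffles)
        assert si == pytest.approx(50.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            t1 = np.sort(rng.uniform(0, 1, rng.integers(5, 200)))
            t2 = np.sort(rng.uniform(0, 1, rng.integers(5, 200)))
            shuffles = [np.sort(rng.uniform(0, 1, 50)) for _ in range(4)]
            half = 0.0025
            expected = (
                brute_force_coincidences(t1, t2, half)
                - np.mean([brute_force_coincidences(t1, s, half) for s in shuffles])
            ) / (t1.size + t2.size) * 100.0
            assert esi(t1, t2, shuffles) == pytest.approx(expected)

    def test_shift_predictor_is_unbiased_for_independent_pairs(self):
        """100 independent 20 Hz Poisson pairs: mean SI% within 3 SE of 0."""
        rng = np.random.default_rng(1)
        vals = []
        for _ in range(100):
            trains = [np.sort(rng.uniform(0, 1, rng.poisson(20))) for _ in range(6)]
            if trains[0].size == 0 or trains[1].size == 0:
                continue
            vals.append(esi(trains[0], trains[1], trains[2:]))
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean()) < 3 * se

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            esi(np.empty(0), np.array([0.5]), [np.array([0.1])])


class TestKernelizedBinless:
    def test_identical_trains_give_one(self):
        t = np.array([0.1, 0.3, 0.35, 0.8])
        assert kernelized_binless(t, t.copy()) == pytest.approx(1.0, abs=1e-12)

    def test_single_spike_closed_form(self):
        """Two single spikes dt apart: cosine = exp(-|dt|/phi)."""
        for dt_ms in (2.0, 5.0, 10.0):
            sim = kernelized_binless(np.array([0.1]), np.array([0.1 + dt_ms / 1000]), phi_ms=5.0)
            assert sim == pytest.approx(np.exp(-dt_ms / 5.0), abs=1e-3)

    def test_empty_train_convention(self):
        assert kernelized_binless(np.empty(0), np.array([0.2])) == 0.0

    def test_grid_refinement_converged(self):
        rng = np.random.default_rng(2)
        t1 = np.sort(rng.uniform(0, 0.5, 20))
        t2 = np.sort(rng.uniform(0, 0.5, 25))
        s1 = kernelized_binless(t1, t2, grid_ms=0.1)
        s2 = kernelized_binless(t1, t2, grid_ms=0.05)
        assert abs(s1 - s2) < 1e-3


class TestPairwiseMatrix:
    @pytest.fixture
    def three_unit_rec(self):
        rng = np.random.default_rng(3)
        spikes = {}
        for u in ("a", "b", "c"):
            for tr in range(5):
                t = np.sort(rng.uniform(0, 2, 30))
                spikes[(u, "s1", tr)] = t
        return EnsembleRecording(
            unit_ids=["a", "b", "c"],
            stimuli=[("s1", "behavioral")],
            trials_per_stimulus=5,
            spikes=spikes,
            stim_onset_s=0.5,
            trial_duration_s=2.0,
        )

    @pytest.mark.parametrize("method", ["esi", "kb"])
    def test_symmetric_with_three_upper_entries(self, three_unit_rec, method):
        pm = pairwise_matrix(three_unit_rec, method=method)
        mat = pm.matrices["s1"]
        iu = np.triu_indices(3, 1)
        assert np.isfinite(mat[iu]).sum() == 3
        np.testing.assert_allclose(mat, mat.T, equal_nan=True)
        feats = upper_triangular_features(pm, ["s1"])
        assert feats.shape == (1, 3)

    def test_planted_sync_pairs_score_higher(self, benchmark_rec):
        """Same-group pairs under class-matched stimuli beat independent
        pairs for both pairwise methods."""
        for method in ("esi", "kb"):
            pm = pairwise_matrix(benchmark_rec, method=method)
            sync_scores, indep_scores = [], []
            for sid in ("B1", "B2", "B3", "B4"):
                m = pm.matrices[sid]
                for i in range(6):
                    for j in range(i + 1, 6):
                        sync_scores.append(m[i, j])
                for i in range(6, 12):
                    for j in range(i + 1, 12):
                        indep_scores.append(m[i, j])
            assert np.nanmean(sync_scores) > np.nanmean(indep_scores)


class TestClustering:
    def test_separable_blobs_cluster_perfectly(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 0.1, (5, 6)), rng.normal(5, 0.1, (5, 6))])
        labels = ["behavioral"] * 5 + ["non_behavioral"] * 5
        rep = cluster_stimuli(X, labels, n_seeds=3, seed=0)
        assert rep.mean_accuracy == 1.0

    def test_accuracy_invariant_to_class_name_swap(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (8, 4))
        l1 = ["behavioral"] * 4 + ["non_behavioral"] * 4
        l2 = ["non_behavioral"] * 4 + ["behavioral"] * 4
        r1 = cluster_stimuli(X, l1, n_seeds=3, seed=0)
        r2 = cluster_stimuli(X, l2, n_seeds=3, seed=0)
        assert r1.accuracies == r2.accuracies

    def test_null_features_stay_in_chance_band(self):
        """iid feature rows carry no class signal: mean accuracy must sit
        in the 2-class chance band."""
        rng = np.random.default_rng(6)
        accs = []
        for s in range(100):
            X = rng.normal(0, 1, (20, 10))
            labels = ["behavioral"] * 10 + ["non_behavioral"] * 10
            rep = cluster_stimuli(X, labels, n_seeds=1, seed=s, use_tsne=False)
            accs.append(rep.mean_accuracy)
        assert 0.5 <= np.mean(accs) <= 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            cluster_stimuli(np.zeros((6, 3)), ["behavioral"] * 6, n_seeds=1)


def _untrained_models(rec, delta_ms=10.0):
    """Freshly initialized (untrained) per-unit models: enough to exercise
    the summary bookkeeping, whose invariants hold for any parameters."""
    split = CVSplit(train_trials=(), val_trial=0, test_trial=1, rotation=0)
    models = {}
    for i, u in enumerate(rec.unit_ids):
        att = AttentionParams.init(rec.n_units, int(delta_ms), rec.n_stimuli, rng=i)
        fl = FlowParams.init(att.hidden_dim + rec.n_stimuli + 1, n_layers=2, width=8, rng=i)
        model = ISIDensityModel(att, fl, bin_ms=1.0, delta_ms=delta_ms, trial_duration_s=rec.trial_duration_s)
        models[u] = [TrainedNeuronModel(unit=u, split=split, model=model, val_nll=0.0)]
    return models


class TestAttentionSummary:
    def test_rows_of_B_are_simplex_vectors(self, tiny_rec):
        models = _untrained_models(tiny_rec)
        summary = attention_summary(models, tiny_rec, eval_trials="val+test")
        valid = ~np.isnan(summary.B).any(axis=1)
        assert valid.any()
        np.testing.assert_allclose(summary.B[valid].sum(axis=1), 1.0, atol=1e-9)
        assert np.all(summary.B[valid] >= 0)

    def test_single_unit_population_gets_all_weight(self):
        spikes = {("a", "s", tr): np.linspace(0.1, 0.9, 12) for tr in range(2)}
        rec = EnsembleRecording(
            unit_ids=["a"],
            stimuli=[("s", "behavioral")],
            trials_per_stimulus=2,
            spikes=spikes,
            stim_onset_s=0.3,
            trial_duration_s=1.0,
        )
        summary = attention_summary(_untrained_models(rec), rec)
        np.testing.assert_allclose(summary.B, 1.0)


class TestAblation:
    @pytest.fixture
    def summary(self):
        rng = np.random.default_rng(7)
        B = rng.dirichlet(np.ones(6), size=8)
        return SyncSummary(
            B=B,
            per_neuron=[B],
            stimulus_ids=[f"s{i}" for i in range(8)],
            unit_ids=[f"u{i}" for i in range(6)],
        )

    @pytest.fixture
    def labels(self):
        return ["behavioral"] * 4 + ["non_behavioral"] * 4

    def test_removing_nothing_reproduces_baseline(self, summary, labels):
        base = cluster_stimuli(summary.B, labels, n_seeds=3, seed=1)
        ablated = ablation_accuracy(summary, labels, remove_units=[], n_seeds=3, seed=1)
        assert ablated.accuracies == base.accuracies

    def test_deterministic_at_fixed_seed(self, summary, labels):
        r1 = ablation_accuracy(summary, labels, ["u2"], n_seeds=3, seed=5)
        r2 = ablation_accuracy(summary, labels, ["u2"], n_seeds=3, seed=5)
        assert r1.accuracies == r2.accuracies

    def test_column_deletion_and_optional_renormalization(self, summary, labels):
        keep = [1, 2, 3, 4, 5]
        B = summary.B[:, keep]
        rep = ablation_accuracy(summary, labels, ["u0"], n_seeds=2, seed=0, use_tsne=False)
        direct = cluster_stimuli(B, labels, n_seeds=2, seed=0, use_tsne=False)
        assert rep.accuracies == direct.accuracies
        B_norm = B / B.sum(axis=1, keepdims=True)
        rep_n = ablation_accuracy(
            summary, labels, ["u0"], n_seeds=2, seed=0, use_tsne=False, renormalize=True
        )
        direct_n = cluster_stimuli(B_norm, labels, n_seeds=2, seed=0, use_tsne=False)
        assert rep_n.accuracies == direct_n.accuracies

    def test_removing_all_units_rejected(self, summary, labels):
        with pytest.raises(ValueError):
            ablation_accuracy(summary, labels, summary.unit_ids)


class TestResponseIndex:
    @pytest.fixture
    def rate_rec(self):
        # deterministic spike counts in the 0-600 ms response window
        def train(n):
            return np.linspace(0.35, 0.85, n) if n else np.empty(0)

        counts = {"odor": 6, "ctrl": 0, "x1": 3, "x2": 3}
        spikes = {("a", s, 0): train(c) for s, c in counts.items() if c}
        return EnsembleRecording(
            unit_ids=["a"],
            stimuli=[("odor", "behavioral"), ("ctrl", "control"), ("x1", "non_behavioral"), ("x2", "non_behavioral")],
            trials_per_stimulus=1,
            spikes=spikes,
            stim_onset_s=0.3,
            trial_duration_s=1.0,
        )

    def test_formula_arithmetic(self, rate_rec):
        # rates: odor 10, ctrl 0, x1 5, x2 5 Hz -> RI = ((10-0)-5)/sd
        rates = np.array([10.0, 0.0, 5.0, 5.0])
        expected = ((10.0 - 0.0) - rates.mean()) / rates.std(ddof=1)
        assert response_index(rate_rec, "a", "odor") == pytest.approx(expected)

    def test_zero_rate_sd_rejected(self):
        spikes = {("a", s, 0): np.linspace(0.35, 0.85, 3) for s in ("odor", "ctrl")}
        rec = EnsembleRecording(
            unit_ids=["a"],
            stimuli=[("odor", "behavioral"), ("ctrl", "control")],
            trials_per_stimulus=1,
            spikes=spikes,
            stim_onset_s=0.3,
            trial_duration_s=1.0,
        )
        with pytest.raises(ValueError, match="SD"):
            response_index(rec, "a", "odor")


class TestPSTH:
    @staticmethod
    def _homogeneous_rec(seed, rate_hz=10.0, extra_evoked=0.0):
        rng = np.random.default_rng(seed)
        spikes = {}
        for tr in range(50):
            t = np.concatenate(
                [
                    rng.uniform(0, 3.0, rng.poisson(rate_hz * 3.0)),
                    rng.uniform(1.0, 1.4, rng.poisson(extra_evoked)),
                ]
            )
            t = np.sort(t)
            t = t[np.concatenate([[True], np.diff(t) > 1e-9])]
            if t.size:
                spikes[("a", "s", tr)] = t
        return EnsembleRecording(
            unit_ids=["a"],
            stimuli=[("s", "behavioral")],
            trials_per_stimulus=50,
            spikes=spikes,
            stim_onset_s=1.0,
            trial_duration_s=3.0,
        )

    def test_homogeneous_firing_z_near_zero(self):
        """10 Hz homogeneous Poisson, 50 trials: the smoothed z-trace is
        flat (typical bin well inside one baseline SD)."""
        _, z = psth_zscore(self._homogeneous_rec(8), "a", "s")
        assert np.mean(np.abs(z)) < 0.5
        assert np.max(np.abs(z)) < 3.0
        assert abs(np.mean(z)) < 0.5

    def test_evoked_response_stands_out_against_null(self):
        _, z_null = psth_zscore(self._homogeneous_rec(0), "a", "s")
        centers, z = psth_zscore(self._homogeneous_rec(0, extra_evoked=20.0), "a", "s")
        assert z.max() > 5 * np.max(np.abs(z_null))
        peak_t = centers[np.argmax(z)]
        assert 1.0 <= peak_t <= 1.6  # response localized to the stimulation window

    def test_smoothing_conserves_mass_away_from_edges(self):
        rng = np.random.default_rng(9)
        spikes = {("a", "s", 0): np.sort(rng.uniform(0.5, 2.5, 100))}
        rec = EnsembleRecording(
            unit_ids=["a"],
            stimuli=[("s", "behavioral")],
            trials_per_stimulus=1,
            spikes=spikes,
            stim_onset_s=1.0,
            trial_duration_s=3.0,
        )
        from scipy.ndimage import gaussian_filter1d

        bin_s = 0.02
        counts, _ = np.histogram(spikes[("a", "s", 0)], bins=np.arange(0, 3.0 + bin_s, bin_s))
        smoothed = gaussian_filter1d(counts.astype(float), 3.0, mode="constant", truncate=3.0)
        assert abs(smoothed.sum() - counts.sum()) / counts.sum() <= 0.01

    def test_zero_baseline_variance_rejected(self):
        rec = EnsembleRecording(
            unit_ids=["a"],
            stimuli=[("s", "behavioral")],
            trials_per_stimulus=1,
            spikes={("a", "s", 0): np.array([2.0, 2.1, 2.2])},
            stim_onset_s=1.0,
            trial_duration_s=3.0,
        )
        with pytest.raises(ValueError, match="baseline"):
            psth_zscore(rec, "a", "s")


class TestDissimilarityIndex:
    @pytest.fixture
    def summary(self):
        B = np.array([[0.0, 0.0], [3.0, 4.0], [1.0, 0.0], [0.0, 0.0]])
        return SyncSummary(B=B, per_neuron=[B], stimulus_ids=["r", "a", "b", "c"], unit_ids=["u0", "u1"])

    def test_pythagorean_distance_and_normalization(self, summary):
        d = dissimilarity_index(summary, "r", ["a", "b", "c"])
        raw = np.array([5.0, 1.0, 0.0])
        np.testing.assert_allclose(
            [d["a"], d["b"], d["c"]], raw / raw.mean()
        )
        assert np.isclose(np.mean(list(d.values())), 1.0)
        assert d["c"] == 0.0  # identical rows

    def test_too_few_comparisons_rejected(self, summary):
        with pytest.raises(ValueError):
            dissimilarity_index(summary, "r", ["a"])
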