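import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stanflow._autodiff import Adam, Tensor, concat
from stanflow.attention import (
    AttentionParams,
    attention_forward,
    encode_context,
    encode_window,
    reweight_window,
    sparsemax,
    spatial_weights,
    temporal_weights,
)


def kkt_projection(z):
    """Independent simplex-projection oracle: enumerate support sets and
    check the KKT conditions of min ||x - z||^2 s.t. x on the simplex."""
    n = len(z)
    best = None
    for mask in itertools.product([0, 1], repeat=n):
        support = [i for i in range(n) if mask[i]]
        if not support:
            continue
        tau = (sum(z[i] for i in support) - 1.0) / len(support)
        x = np.zeros(n)
        ok = True
        for i in range(n):
            if i in support:
                x[i] = z[i] - tau
                ok &= x[i] >= -1e-12
            else:
                ok &= z[i] - tau <= 1e-12
        if ok:
            best = x
    return best


class TestSparsemax:
    def test_simplex_inputs_are_fixed_points(self):
        v = np.array([0.5, 0.3, 0.2])
        np.testing.assert_allclose(sparsemax(v), v, atol=1e-12)

    def test_gap_one_yields_one_hot(self):
        np.testing.assert_allclose(sparsemax([2.0, 0.0]), [1.0, 0.0])

    def test_symmetry(self):
        for c in (-3.0, 0.0, 1.7):
            np.testing.assert_allclose(sparsemax([c, c, c]), np.ones(3) / 3)

    def test_matches_kkt_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(1, 9)
            z = rng.normal(0, 2, n)
            np.testing.assert_allclose(sparsemax(z), kkt_projection(z), atol=1e-8)

    def test_one_hot_when_one_entry_leads_by_one(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(2, 8)
            z = rng.uniform(-1, 1, n)
            k = rng.integers(0, n)
            z[k] = z.max() + 1.0 + rng.uniform(0, 0.5)
            expected = np.zeros(n)
            expected[k] = 1.0
            np.testing.assert_allclose(sparsemax(z), expected, atol=1e-12)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            sparsemax([])

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=12),
        st.floats(-10, 10),
    )
    def test_simplex_output_and_shift_invariance(self, logits, shift):
        """Output is on the simplex and invariant to constant shifts of
        the logits (a property of the simplex projection)."""
        z = np.asarray(logits)
        out = sparsemax(z)
        assert np.all(out >= 0)
        assert np.isclose(out.sum(), 1.0)
        np.testing.assert_allclose(sparsemax(z + shift), out, atol=1e-9)


@pytest.fixture
def params():
    return AttentionParams.init(n_units=4, window_bins=10, n_stimuli=3, embed_dim=5, hidden_dim=6, rng=0)


class TestTemporalWeights:
    def test_zero_heads_give_uniform_alpha(self, params):
        params.Walpha.data[:] = 0.0
        params.balpha.data[:] = 0.0
        window = np.random.default_rng(0).poisson(0.5, (4, 10)).astype(float)
        alpha, h_last, hs = temporal_weights(params, window)
        np.testing.assert_allclose(alpha, np.ones(10) / 10)
        assert hs.shape == (10, 6)
        np.testing.assert_allclose(hs[-1], h_last)

    def test_alpha_on_simplex_for_random_draws(self, params):
        rng = np.random.default_rng(2)
        for _ in range(100):
            alpha, _, _ = temporal_weights(params, rng.poisson(0.7, (4, 10)).astype(float))
            assert np.all(alpha >= 0)
            assert np.isclose(alpha.sum(), 1.0)

    def test_unit_permutation_equivariance(self, params):
        """Permuting window rows together with the input weights of f1
        leaves the temporal weights unchanged."""
        rng = np.random.default_rng(3)
        window = rng.poisson(0.6, (4, 10)).astype(float)
        alpha, _, _ = temporal_weights(params, window)
        perm = np.array([2, 0, 3, 1])
        params.f1["Wx"].data = params.f1["Wx"].data[perm]
        alpha_p, _, _ = temporal_weights(params, window[perm])
        np.testing.assert_allclose(alpha_p, alpha, atol=1e-12)


class TestSpatialWeights:
    def test_single_unit_gets_weight_one(self):
        p = AttentionParams.init(1, 10, 3, embed_dim=5, hidden_dim=6, rng=0)
        beta = spatial_weights(p, np.zeros(6), np.ones((1, 5)), np.eye(3)[0])
        np.testing.assert_allclose(beta, [1.0])

    def test_identical_embeddings_give_uniform_beta(self, params):
        emb = np.tile(np.array([0.3, -0.2, 0.5, 0.0, 1.0]), (4, 1))
        beta = spatial_weights(params, np.zeros(6), emb, np.eye(3)[1])
        np.testing.assert_allclose(beta, np.ones(4) / 4)

    def test_dominant_logit_gives_one_hot(self, params):
        # drive one unit's tanh logit to ~+1 and the others to ~-1
        params.Wbeta_e.data[:] = 0.0
        params.Wbeta_e.data[0, 0] = 1.0
        params.Wbeta_h.data[:] = 0.0
        params.Wbeta_q.data[:] = 0.0
        params.bbeta.data[:] = 0.0
        emb = np.full((4, 5), -10.0)
        emb[2, 0] = 10.0
        beta = spatial_weights(params, np.zeros(6), emb, np.eye(3)[0])
        np.testing.assert_allclose(beta, [0, 0, 1, 0], atol=1e-8)

    def test_empty_population_rejected(self, params):
        with pytest.raises(ValueError):
            spatial_weights(params, np.zeros(6), np.empty((0, 5)), np.eye(3)[0])


class TestReweighting:
    def test_uniform_weights_are_identity(self):
        window = np.arange(12.0).reshape(3, 4)
        out = reweight_window(window, np.ones(4) / 4, np.ones(3) / 3)
        np.testing.assert_allclose(out, window)

    def test_one_hot_beta_masks_other_units(self):
        window = np.ones((4, 5))
        out = reweight_window(window, np.ones(5) / 5, np.array([0.0, 0, 0, 1.0]))
        assert np.all(out[:3] == 0)
        assert np.all(out[3] > 0)

    def test_total_mass_identity_against_direct_loop(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n, d = rng.integers(2, 6), rng.integers(2, 8)
            window = rng.poisson(1.0, (n, d)).astype(float)
            alpha = rng.dirichlet(np.ones(d))
            beta = rng.dirichlet(np.ones(n))
            out = reweight_window(window, alpha, beta)
            direct = sum(
                n * d * beta[i] * alpha[t] * window[i, t]
                for i in range(n)
                for t in range(d)
            )
            assert np.isclose(out.sum(), direct)

    def test_non_simplex_weights_rejected(self):
        with pytest.raises(ValueError, match="simplex"):
            reweight_window(np.ones((2, 3)), np.array([0.5, 0.2, 0.2]), np.array([0.5, 0.5]))


class TestContextEncoder:
    def test_deterministic_and_zero_window_fixed(self, params):
        z = encode_context(params, np.zeros((4, 10)))
        np.testing.assert_array_equal(z, encode_context(params, np.zeros((4, 10))))
        window = np.random.default_rng(5).poisson(0.5, (4, 10)).astype(float)
        assert not np.allclose(encode_context(params, window), z)

    def test_context_sensitive_to_spike_position(self, params):
        w1 = np.zeros((4, 10))
        w1[1, 2] = 1.0
        w2 = np.zeros((4, 10))
        w2[1, 7] = 1.0
        c1 = encode_context(params, w1)
        c2 = encode_context(params, w2)
        assert np.max(np.abs(c1 - c2)) > 1e-6

    def test_ops_compose_to_full_forward(self, params):
        """The single-window ops reproduce the batched encoder pass."""
        rng = np.random.default_rng(6)
        window = rng.poisson(0.5, (4, 10)).astype(float)
        q = np.eye(3)[2]
        out = encode_window(params, window, q)
        alpha, h_last, _ = temporal_weights(params, window)
        beta = spatial_weights(params, h_last, out.embedding, q)
        rw = reweight_window(window, alpha, beta)
        np.testing.assert_allclose(out.alpha, alpha, atol=1e-12)
        np.testing.assert_allclose(out.beta, beta, atol=1e-12)
        np.testing.assert_allclose(out.reweighted, rw, atol=1e-10)
        np.testing.assert_allclose(out.context, encode_context(params, rw), atol=1e-10)


class TestDifferentiability:
    def test_finite_difference_gradients(self, params):
        """Gradient flows to every parameter block (no detached paths)."""
        rng = np.random.default_rng(7)
        windows = rng.poisson(0.5, (5, 4, 10)).astype(float)
        q = np.eye(3)[rng.integers(0, 3, 5)]

        def loss_fn():
            out = attention_forward(params, windows, q)
            return (out["context"] * out["context"]).mean() + (
                out["alpha"] * Tensor(np.linspace(0, 1, 10))
            ).sum() + (out["beta"] * Tensor(np.linspace(1, 0, 4))).sum()

        loss = loss_fn()
        loss.backward()
        rng_idx = np.random.default_rng(8)
        for p in params.parameters():
            assert p.grad is not None
            ix = tuple(rng_idx.integers(0, s) for s in p.data.shape)
            eps = 1e-6
            old = p.data[ix]
            p.data[ix] = old + eps
            lp = float(loss_fn().data)
            p.data[ix] = old - eps
            lm = float(loss_fn().data)
            p.data[ix] = old
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - p.grad[ix]) < 1e-4 * (1 + abs(fd))

    def test_weights_stay_on_simplex_after_gradient_updates(self, params):
        rng = np.random.default_rng(9)
        windows = rng.poisson(0.5, (6, 4, 10)).astype(float)
        q = np.eye(3)[rng.integers(0, 3, 6)]
        opt = Adam(params.parameters(), lr=0.05)
        for _ in range(5):
            out = attention_forward(params, windows, q)
            loss = (out["context"] ** 2).mean() - (out["beta"] ** 2).sum()
            opt.zero_grad()
            loss.backward()
            opt.step()
        out = attention_forward(params, windows, q)
        np.testing.assert_allclose(out["alpha"].data.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(out["beta"].data.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(out["beta"].data >= 0)
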