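"""Unit and property tests for the probabilistic max-pooling CRBM."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdbntrack import crbm
from cdbntrack.crbm import (
    CRBMLayer,
    ConvRBM,
    HiddenState,
    TrainingDivergedError,
    cd1_gradient,
    energy,
    hidden_conditionals,
    init_layer,
    pooled_representation,
    sample_hidden,
    train_layer,
    visible_conditionals,
)


def naive_energy(v, h, layer):
    """Triple-loop transcription of the energy function (oracle)."""
    v = np.atleast_3d(v)
    W, b, c = layer.weights, layer.hidden_bias, layer.visible_bias
    K, nw = layer.n_filters, layer.filter_size
    nh = v.shape[0] - nw + 1
    E = 0.5 * (v**2).sum() - c * v.sum()
    for k in range(K):
        for i in range(nh):
            for j in range(nh):
                acc = 0.0
                for r in range(nw):
                    for s in range(nw):
                        for ch in range(v.shape[2]):
                            acc += W[k, r, s, ch] * v[i + r, j + s, ch]
                E -= h[i, j, k] * (acc + b[k])
    return E


def enumerate_conditionals(v, layer):
    """Exact P(h_ij=1 | v) by summing the Boltzmann distribution over all
    valid hidden configurations (one outcome of C^2+1 per block)."""
    C = layer.pool_size
    nh = layer.hidden_side(np.atleast_3d(v).shape[0])
    nP = nh // C
    K = layer.n_filters
    blocks = [(k, bi, bj) for k in range(K) for bi in range(nP) for bj in range(nP)]
    marg = np.zeros((nh, nh, K))
    Z = 0.0
    n_outcomes = C * C + 1
    for choice in itertools.product(range(n_outcomes), repeat=len(blocks)):
        h = np.zeros((nh, nh, K))
        for (k, bi, bj), c in zip(blocks, choice):
            if c < C * C:
                i, j = divmod(c, C)
                h[bi * C + i, bj * C + j, k] = 1.0
        w = np.exp(-energy(v, h, layer))
        Z += w
        marg += w * h
    return marg / Z


class TestEnergy:
    def test_all_zero_hidden_only_quadratic_term(self):
        layer = CRBMLayer(np.zeros((1, 1, 1, 1)), np.zeros(1), 0.0, pool_size=2)
        v = np.ones((2, 2))
        h = np.zeros((2, 2, 1))
        assert energy(v, h, layer) == pytest.approx(2.0)

    def test_visible_bias_term(self):
        layer = CRBMLayer(np.zeros((1, 1, 1, 1)), np.zeros(1), 1.0, pool_size=2)
        v = np.ones((2, 2))
        h = np.zeros((2, 2, 1))
        assert energy(v, h, layer) == pytest.approx(-2.0)

    def test_matches_naive_triple_loop(self, small_layer):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(4, 4))
        up, off = hidden_conditionals(v, small_layer)
        h = sample_hidden(up, off, rng)
        assert energy(v, h, small_layer) == pytest.approx(
            naive_energy(v, h.hidden, small_layer), rel=1e-12)

    def test_rejects_block_constraint_violation(self, small_layer):
        v = np.zeros((4, 4))
        h = np.zeros((2, 2, 1))
        h[0, 0, 0] = h[0, 1, 0] = 1  # two active units in one 2x2 block
        with pytest.raises(ValueError, match="block constraint"):
            energy(v, h, small_layer)

    def test_energy_consistent_with_enumerated_distribution(self, small_layer):
        # log unnormalized probability differences must equal energy gaps
        rng = np.random.default_rng(3)
        v = rng.normal(size=(4, 4))
        h0 = np.zeros((2, 2, 1))
        h1 = np.zeros((2, 2, 1))
        h1[0, 0, 0] = 1
        gap = energy(v, h1, small_layer) - energy(v, h0, small_layer)
        up, off = hidden_conditionals(v, small_layer)
        # single 2x2 block: P(h_00)/P(all off) = exp(-gap)
        assert up[0, 0, 0] / off[0, 0, 0] == pytest.approx(np.exp(-gap))


class TestHiddenConditionals:
    def test_uniform_when_unparameterized(self):
        layer = CRBMLayer(np.zeros((1, 3, 3, 1)), np.zeros(1), 0.0, pool_size=2)
        v = np.ones((4, 4))
        up, off = hidden_conditionals(v, layer)
        assert np.allclose(up, 0.2)
        assert np.allclose(off, 0.2)

    def test_large_bias_closed_form(self):
        layer = CRBMLayer(np.zeros((1, 3, 3, 1)), np.full(1, 10.0), 0.0,
                          pool_size=2)
        up, off = hidden_conditionals(np.zeros((4, 4)), layer)
        expected_unit = np.exp(10.0) / (1.0 + 4 * np.exp(10.0))
        expected_off = 1.0 / (1.0 + 4 * np.exp(10.0))
        assert up[0, 0, 0] == pytest.approx(expected_unit, rel=1e-6)
        assert off[0, 0, 0] == pytest.approx(expected_off, rel=1e-6)
        assert up[0, 0, 0] == pytest.approx(0.2499972, abs=1e-6)
        assert off[0, 0, 0] == pytest.approx(1.135e-5, abs=1e-7)

    def test_matches_exhaustive_enumeration(self, small_layer):
        rng = np.random.default_rng(7)
        v = rng.normal(size=(6, 6))  # 4x4 hidden grid, 4 blocks -> 625 configs
        up, _ = hidden_conditionals(v, small_layer)
        exact = enumerate_conditionals(v, small_layer)
        assert np.abs(up - exact).max() < 1e-8

    def test_block_probabilities_sum_to_one(self):
        rng = np.random.default_rng(11)
        layer = init_layer(3, 3, 2, pool_size=2, weight_scale=1.0, rng=rng)
        v = rng.normal(size=(8, 8, 2))
        up, off = hidden_conditionals(v, layer)
        blocks = crbm._block_view(up[None], 2)[0]
        assert np.abs(blocks.sum(-1) + off - 1.0).max() < 1e-14

    def test_shift_invariance_of_block_softmax(self, small_layer):
        # adding a constant to every block input leaves probabilities fixed
        rng = np.random.default_rng(2)
        v = rng.normal(size=(6, 6))
        up1, off1 = hidden_conditionals(v, small_layer)
        shifted = small_layer.copy()
        shifted.hidden_bias = small_layer.hidden_bias + 300.0  # would overflow naively
        up2, off2 = hidden_conditionals(v, shifted)
        assert np.isfinite(up2).all() and np.isfinite(off2).all()
        # and an explicit shift comparison at moderate scale
        shifted.hidden_bias = small_layer.hidden_bias + 5.0
        up3, _ = hidden_conditionals(v, shifted)
        odds1 = up1 / (1 - up1)
        odds3 = up3 / (1 - up3)
        assert np.allclose(np.log(odds3) - np.log(odds1), 0, atol=10)  # finite

    @given(shift=st.floats(-50, 50))
    @settings(max_examples=20, deadline=None)
    def test_relative_probabilities_invariant_under_shift(self, shift):
        rng = np.random.default_rng(4)
        layer = init_layer(1, 3, 1, pool_size=2, weight_scale=0.5, rng=rng)
        v = rng.normal(size=(4, 4))
        up1, off1 = hidden_conditionals(v, layer)
        layer2 = layer.copy()
        layer2.hidden_bias = layer.hidden_bias + shift
        up2, off2 = hidden_conditionals(v, layer2)
        # unit probabilities renormalized among units are shift-invariant
        r1 = up1 / up1.sum()
        r2 = up2 / up2.sum()
        assert np.allclose(r1, r2, atol=1e-9)


class TestSampleHidden:
    def test_all_off_block_stays_off(self):
        up = np.zeros((2, 2, 1))
        off = np.ones((1, 1, 1))
        h = sample_hidden(up, off, np.random.default_rng(0), pool_size=2)
        assert h.hidden.sum() == 0
        assert h.pooling.sum() == 0

    def test_empirical_frequencies_match_uniform(self):
        up = np.full((2, 2, 1), 0.2)
        off = np.full((1, 1, 1), 0.2)
        rng = np.random.default_rng(1)
        n = 100_000
        counts = np.zeros((2, 2))
        for _ in range(n):
            counts += sample_hidden(up, off, rng, pool_size=2).hidden[:, :, 0]
        p = counts / n
        sigma = np.sqrt(0.2 * 0.8 / n)
        assert np.abs(p - 0.2).max() < 3 * sigma

    def test_same_seed_reproduces_state(self, small_layer):
        v = np.random.default_rng(5).normal(size=(6, 6))
        up, off = hidden_conditionals(v, small_layer)
        h1 = sample_hidden(up, off, np.random.default_rng(42))
        h2 = sample_hidden(up, off, np.random.default_rng(42))
        assert np.array_equal(h1.hidden, h2.hidden)
        assert np.array_equal(h1.pooling, h2.pooling)

    def test_samples_respect_block_constraint(self, small_layer):
        rng = np.random.default_rng(9)
        v = rng.normal(size=(6, 6))
        up, off = hidden_conditionals(v, small_layer)
        for _ in range(50):
            sample_hidden(up, off, rng).validate()


class TestVisibleConditionals:
    def test_all_zero_hidden_gives_constant_bias(self, small_layer):
        h = HiddenState(np.zeros((4, 4, 1)), np.zeros((2, 2, 1)), 2)
        mean = visible_conditionals(h, small_layer)
        assert np.allclose(mean, small_layer.visible_bias)

    def test_single_unit_stamps_the_filter(self, small_layer):
        h = np.zeros((4, 4, 1))
        h[1, 2, 0] = 1.0
        mean = visible_conditionals(h, small_layer)
        expected = np.full((6, 6, 1), small_layer.visible_bias)
        expected[1:4, 2:5, 0] += small_layer.weights[0, :, :, 0]
        assert np.allclose(mean, expected)

    def test_matches_naive_full_convolution(self):
        rng = np.random.default_rng(13)
        layer = init_layer(3, 3, 2, pool_size=2, weight_scale=1.0, rng=rng)
        h = (rng.random((4, 4, 3)) < 0.3).astype(float)
        mean = visible_conditionals(h, layer)
        naive = np.full((6, 6, 2), layer.visible_bias)
        for k in range(3):
            for i in range(4):
                for j in range(4):
                    naive[i : i + 3, j : j + 3, :] += h[i, j, k] * layer.weights[k]
        assert np.allclose(mean, naive)


class TestPooledRepresentation:
    def test_uniform_case_constant(self):
        layer = CRBMLayer(np.zeros((1, 3, 3, 1)), np.zeros(1), 0.0, pool_size=2)
        pooled = pooled_representation(np.ones((4, 4)), layer)
        assert np.allclose(pooled, 0.8)

    def test_output_geometry_and_range(self):
        rng = np.random.default_rng(17)
        layer = init_layer(6, 5, 1, pool_size=2, rng=rng)
        pooled = pooled_representation(rng.normal(size=(32, 32)), layer)
        assert pooled.shape == (14, 14, 6)
        assert (pooled > 0).all() and (pooled < 1).all()

    def test_equals_one_minus_pool_off(self, small_layer):
        v = np.random.default_rng(19).normal(size=(6, 6))
        _, off = hidden_conditionals(v, small_layer)
        assert np.allclose(pooled_representation(v, small_layer), 1.0 - off)


class TestCD1:
    def test_empty_batch_rejected(self, small_layer):
        with pytest.raises(ValueError, match="empty"):
            cd1_gradient([], small_layer, 0.0, np.random.default_rng(0))

    def test_sparsity_pushes_bias_down_when_too_active(self):
        layer = CRBMLayer(np.zeros((1, 3, 3, 1)), np.full(1, 2.0), 0.0,
                          pool_size=2, sparsity_target=0.003)
        v = np.zeros((4, 4))
        # without weights the CD term vanishes in expectation only; use
        # a strong penalty so the sparsity sign dominates
        g = cd1_gradient([v], layer, 100.0, np.random.default_rng(0))
        assert g.mean_activation[0] > layer.sparsity_target
        assert g.hidden_bias[0] < 0

    def test_near_fixed_point_increments_small(self):
        # a zero-weight model whose activation equals the target: bias at
        # the value where the 5-way softmax matches the sparsity target
        target = 0.15
        b = np.log(target / (1 - 4 * target))
        layer = CRBMLayer(np.zeros((1, 3, 3, 1)), np.full(1, b), 0.0,
                          pool_size=2, sparsity_target=target)
        v = np.zeros((4, 4))
        g = cd1_gradient([v] * 64, layer, 1.0, np.random.default_rng(0))
        assert abs(g.mean_activation[0] - target) < 0.05
        assert abs(g.hidden_bias[0]) < 0.05
        assert np.abs(g.weights).max() < 0.05

    def test_cd1_aligns_with_exact_likelihood_gradient(self, small_layer):
        """Averaged CD-1 increments should point along the exact gradient
        of the log-likelihood, computed by finite differences over the
        enumerated partition function of a tiny CRBM."""
        rng = np.random.default_rng(23)
        data = [rng.normal(size=(4, 4)) * 0.8 for _ in range(4)]

        def exact_loglik(layer):
            # visible units are continuous; compare unnormalized data terms
            # against the hidden-summed free energy: log sum_h exp(-E(v,h))
            # minus log Z is intractable in v, but the v-independent part
            # cancels in parameter derivatives of sum_v log p(v) computed
            # with a common Gaussian quadrature over a fixed grid of v.
            total = 0.0
            grid = data  # evaluate likelihood ratios on the data points
            for v in grid:
                total += _log_free_energy(v, layer)
            # normalizer: integrate exp(-free energy) over a sample cloud
            cloud = [rng2.normal(size=(4, 4)) for _ in range(400)]
            fes = np.array([_log_free_energy(v, layer) for v in cloud])
            gauss = np.array([-0.5 * (v**2).sum() for v in cloud])
            logZ = np.log(np.mean(np.exp(fes - gauss))) if False else \
                _logmeanexp(fes - gauss)
            return total - len(grid) * logZ

        def _log_free_energy(v, layer):
            # log sum over valid h of exp(-E(v,h)) via block factorization
            up_input = crbm.bottom_up_input(v, layer)[0]
            blocks = crbm._block_view(up_input[None], layer.pool_size)[0]
            m = np.maximum(blocks.max(-1), 0.0)
            lse = m + np.log(np.exp(-m) + np.exp(blocks - m[..., None]).sum(-1))
            return float(-0.5 * (np.atleast_3d(v) ** 2).sum()
                         + layer.visible_bias * v.sum() + lse.sum())

        def _logmeanexp(a):
            m = a.max()
            return float(m + np.log(np.mean(np.exp(a - m))))

        rng2 = np.random.default_rng(29)
        eps = 1e-4
        exact_grad = np.zeros_like(small_layer.weights)
        for idx in np.ndindex(small_layer.weights.shape):
            for sgn, store in ((1, "p"), (-1, "m")):
                pert = small_layer.copy()
                pert.weights[idx] += sgn * eps
                rng2 = np.random.default_rng(29)  # common random numbers
                val = exact_loglik(pert)
                if sgn == 1:
                    vp = val
                else:
                    exact_grad[idx] = (vp - val) / (2 * eps)

        cd = np.zeros_like(small_layer.weights)
        for s in range(200):
            g = cd1_gradient(data, small_layer, 0.0, np.random.default_rng(s))
            cd += g.weights
        cd /= 200
        cos = float((cd * exact_grad).sum()
                    / (np.linalg.norm(cd) * np.linalg.norm(exact_grad)))
        assert cos > 0.0


class TestTrainLayer:
    def test_zero_epochs_returns_initialization(self, standardized_patches):
        rng = np.random.default_rng(0)
        layer = init_layer(4, 5, 1, rng=rng)
        trained, trace = train_layer(standardized_patches[:32], layer,
                                     n_epochs=0, rng=rng)
        assert np.array_equal(trained.weights, layer.weights)
        assert trace.reconstruction_error == []

    def test_oriented_bars_recover_orientations(self):
        # patches containing a single oriented bar; at least half the
        # learned filters should correlate strongly with some bar
        rng = np.random.default_rng(31)
        bars = []
        templates = []
        for angle in (0, 90):
            t = np.zeros((8, 8))
            if angle == 0:
                t[3:5, :] = 1.0
            else:
                t[:, 3:5] = 1.0
            templates.append((t - t.mean()) / t.std())
        for _ in range(200):
            t = templates[rng.integers(2)].copy()
            bars.append(t + rng.normal(0, 0.15, size=t.shape))
        V = np.stack([b[:, :, None] for b in bars])
        layer = init_layer(4, 5, 1, pool_size=2, sparsity_target=0.05, rng=rng)
        trained, _ = train_layer(V, layer, n_epochs=40, sparsity_weight=1.0,
                                 learning_rate=0.05, rng=rng)
        hits = 0
        for k in range(4):
            f = trained.weights[k, :, :, 0]
            best = 0.0
            for t in templates:
                for i in range(4):
                    for j in range(4):
                        win = t[i : i + 5, j : j + 5]
                        r = np.corrcoef(f.ravel(), win.ravel())[0, 1]
                        best = max(best, abs(r))
            hits += best > 0.5
        assert hits >= 2

    def test_divergence_reported_with_epoch(self, standardized_patches):
        rng = np.random.default_rng(0)
        layer = init_layer(2, 5, 1, rng=rng)
        with pytest.raises(TrainingDivergedError):
            train_layer(standardized_patches[:16], layer, n_epochs=30,
                        learning_rate=1e12, rng=rng)

    def test_sparsity_monotone_in_weight(self, standardized_patches):
        finals = []
        for sw in (0.0, 3.0, 30.0):
            rng = np.random.default_rng(5)
            layer = init_layer(4, 5, 1, sparsity_target=0.003, rng=rng)
            _, trace = train_layer(standardized_patches[:100], layer,
                                   n_epochs=8, sparsity_weight=sw, rng=rng)
            finals.append(float(np.mean(trace.mean_activation[-1])))
        assert finals[0] > finals[1] > finals[2]


class TestConvRBMEstimator:
    def test_fit_transform_shapes(self, standardized_patches):
        est = ConvRBM(n_filters=4, n_epochs=2, random_state=0)
        out = est.fit_transform(standardized_patches[:32])
        assert out.shape == (32, 14, 14, 4)
        assert ((out > 0) & (out < 1)).all()

    def test_get_params_roundtrip(self):
        est = ConvRBM(n_filters=6, sparsity_target=0.01)
        params = est.get_params()
        assert params["n_filters"] == 6
        est2 = ConvRBM(**params)
        assert est2.sparsity_target == 0.01


class TestSerialization:
    def test_layer_roundtrip_bit_exact(self, tmp_path, small_layer):
        path = tmp_path / "layer.npz"
        crbm.save_layer(small_layer, path)
        loaded = crbm.load_layer(path)
        assert np.array_equal(loaded.weights, small_layer.weights)
        assert np.array_equal(loaded.hidden_bias, small_layer.hidden_bias)
        assert loaded.visible_bias == small_layer.visible_bias
        assert loaded.pool_size == small_layer.pool_size
        assert loaded.sparsity_target == small_layer.sparsity_target
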