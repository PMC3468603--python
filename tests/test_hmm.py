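"""HMM emissions, transitions, inference oracle, purity estimation,
bound updates, EM fitting and segment extraction."""

import itertools

import numpy as np
import pytest

from oligocna.hmm import (
    DecodingResult,
    HMMParams,
    I_CNLOH,
    I_GAIN,
    I_LOSS,
    I_NORMAL,
    emission_log_matrix,
    estimate_purity,
    fit_hmm,
    forward_backward,
    genotype_weights,
    het_band_deviation,
    segments_from_decoding,
    transition_matrix,
    update_bounds,
    viterbi_decode,
)
from oligocna.preprocess import preprocess_pair
from oligocna.synthetic import (
    ScenarioTemplate,
    TruthProfile,
    expand_template,
    lrr_mean,
    make_probe_set,
    simulate_pair,
    state_track,
)
from oligocna.types import (
    CNState,
    GENO_AB,
    N_STATES,
    PairedSample,
    ProbeSet,
    SampleIntensities,
    STATE_INDEX,
    STATE_ORDER,
)


def _tiny_probes(n, spacing=1_000_000):
    return ProbeSet(
        snp_id=np.array([f"rs{i}" for i in range(n)], dtype=object),
        chrom=np.array(["1"] * n, dtype=object),
        pos=np.arange(1, n + 1) * spacing,
        gc_frac=np.full(n, 0.5),
        pop_b_freq=np.full(n, 0.5),
    )


class TestEmissions:
    def test_normal_state_maximal_at_normal_signal(self):
        """A clean diploid-looking probe scores highest under NORMAL."""
        params = HMMParams(p=1.0, sigma_baf=0.02)
        params.sigma_lrr[:] = 0.05
        geno_w = np.array([[0.0, 1.0, 0.0]])
        m = emission_log_matrix(
            np.array([0.0]), np.array([0.5]), geno_w, params
        )
        assert m[0].argmax() == I_NORMAL

    def test_homdel_baf_term_uniform(self):
        params = HMMParams(p=0.8)
        geno_w = genotype_weights(None, np.array([0.5, 0.5, 0.5]))
        m = emission_log_matrix(
            np.array([np.nan] * 3), np.array([0.05, 0.5, 0.93]), geno_w, params
        )
        homdel_col = m[:, STATE_INDEX[CNState.HOMDEL]]
        np.testing.assert_allclose(homdel_col, homdel_col[0], atol=1e-12)

    def test_baf_mixture_integrates_to_one(self):
        """The per-state BAF density integrates to 1 over [0, 1]."""
        params = HMMParams(p=0.7, sigma_baf=0.04, pi_o=0.05)
        grid = np.linspace(0, 1, 20001)
        geno_w = genotype_weights(None, np.full(grid.size, 0.3))
        m = emission_log_matrix(
            np.full(grid.size, np.nan), grid, geno_w, params
        )
        for z in range(N_STATES):
            integral = np.trapezoid(np.exp(m[:, z]), grid)
            assert integral == pytest.approx(1.0, abs=1e-3)

    def test_missing_baf_reduces_to_lrr_term(self):
        params = HMMParams(p=0.8)
        geno_w = genotype_weights(None, np.array([0.5]))
        m_missing = emission_log_matrix(
            np.array([-0.5]), np.array([np.nan]), geno_w, params
        )
        lrr_only = (
            -0.5 * ((-0.5 - params.mu_lrr) / params.sigma_lrr) ** 2
            - np.log(params.sigma_lrr * np.sqrt(2 * np.pi))
        )
        np.testing.assert_allclose(m_missing[0], lrr_only, atol=1e-12)


class TestTransitions:
    def test_zero_distance_identity(self):
        A = transition_matrix(0.0, HMMParams())
        np.testing.assert_allclose(A, np.eye(N_STATES), atol=1e-12)

    def test_infinite_distance_stationary(self):
        params = HMMParams()
        A = transition_matrix(1e18, params)
        for i in range(N_STATES):
            np.testing.assert_allclose(A[i], params.pi_z, atol=1e-12)

    def test_diagonal_at_one_length_scale_uniform_pi(self):
        params = HMMParams(pi_z=np.full(6, 1 / 6), L=5e6)
        A = transition_matrix(5e6, params)
        expected = np.exp(-1) + (1 - np.exp(-1)) / 6
        np.testing.assert_allclose(np.diag(A), expected, atol=1e-9)
        assert expected == pytest.approx(0.473233, abs=1e-6)

    def test_rows_sum_to_one(self):
        A = transition_matrix(3.7e6, HMMParams())
        np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-12)


def _enumeration_loglik(logB, rhos, pi, live_states):
    """Brute-force log-sum over all state paths (the independent oracle)."""
    n = logB.shape[0]
    total = -np.inf
    for path in itertools.product(live_states, repeat=n):
        lp = np.log(pi[path[0]]) + logB[0, path[0]]
        for t in range(1, n):
            rho = rhos[t]
            a = rho * (path[t] == path[t - 1]) + (1 - rho) * pi[path[t]]
            lp += np.log(a) + logB[t, path[t]]
        total = np.logaddexp(total, lp)
    return total


class TestForwardBackwardOracle:
    def _setup(self, n, seed):
        probes = _tiny_probes(n)
        rng = np.random.default_rng(seed)
        tumor = SampleIntensities(
            "t", rng.normal(0, 0.5, n), np.clip(rng.random(n), 0.01, 0.99)
        )
        # confine the chain to 3 live states via the stationary distribution
        pi = np.zeros(N_STATES)
        live = [I_LOSS, I_NORMAL, I_CNLOH]
        pi[live] = [0.3, 0.5, 0.2]
        params = HMMParams(p=0.7, pi_z=pi, L=2e6)
        return probes, tumor, params, live

    @pytest.mark.parametrize("n", [1, 2, 5, 8])
    def test_forward_equals_path_enumeration(self, n):
        probes, tumor, params, live = self._setup(n, seed=n)
        ll, gamma = forward_backward(probes, tumor, None, params)
        geno_w = genotype_weights(None, probes.pop_b_freq)
        logB = emission_log_matrix(tumor.lrr, tumor.baf, geno_w, params)
        rhos = np.exp(-np.diff(probes.pos, prepend=probes.pos[0]) / params.L)
        oracle = _enumeration_loglik(logB, rhos, params.pi_z, live)
        assert ll == pytest.approx(oracle, abs=1e-9)

    def test_single_probe_closed_form(self):
        probes, tumor, params, live = self._setup(1, seed=3)
        ll, gamma = forward_backward(probes, tumor, None, params)
        geno_w = genotype_weights(None, probes.pop_b_freq)
        logB = emission_log_matrix(tumor.lrr, tumor.baf, geno_w, params)
        expected = np.log(np.sum(params.pi_z * np.exp(logB[0])))
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_posteriors_sum_to_one(self):
        probes, tumor, params, _ = self._setup(8, seed=5)
        _, gamma = forward_backward(probes, tumor, None, params)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_posterior_matches_enumeration(self):
        """Per-probe posteriors agree with the brute-force path sum."""
        probes, tumor, params, live = self._setup(5, seed=9)
        _, gamma = forward_backward(probes, tumor, None, params)
        geno_w = genotype_weights(None, probes.pop_b_freq)
        logB = emission_log_matrix(tumor.lrr, tumor.baf, geno_w, params)
        rhos = np.exp(-np.diff(probes.pos, prepend=probes.pos[0]) / params.L)
        n = 5
        post = np.zeros((n, N_STATES))
        for path in itertools.product(live, repeat=n):
            lp = np.log(params.pi_z[path[0]]) + logB[0, path[0]]
            for t in range(1, n):
                rho = rhos[t]
                a = rho * (path[t] == path[t - 1]) + (1 - rho) * params.pi_z[path[t]]
                lp += np.log(a) + logB[t, path[t]]
            for t in range(n):
                post[t, path[t]] += np.exp(lp)
        post /= post.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(gamma, post, atol=1e-9)

    def test_chromosomes_independent(self):
        """Log-likelihood over two chromosomes = sum of per-chromosome values."""
        n = 6
        half = ProbeSet(
            snp_id=np.array([f"rs{i}" for i in range(n)], dtype=object),
            chrom=np.array(["1"] * 3 + ["2"] * 3, dtype=object),
            pos=np.array([1e6, 2e6, 3e6, 1e6, 2e6, 3e6]).astype(np.int64),
            gc_frac=np.full(n, 0.5),
            pop_b_freq=np.full(n, 0.5),
        )
        rng = np.random.default_rng(0)
        tumor = SampleIntensities("t", rng.normal(0, 0.3, n), rng.random(n))
        params = HMMParams(p=0.8)
        ll, _ = forward_backward(half, tumor, None, params)
        parts = 0.0
        for sl in (slice(0, 3), slice(3, 6)):
            sub = ProbeSet(
                snp_id=half.snp_id[sl], chrom=np.array(["1"] * 3, dtype=object),
                pos=half.pos[sl], gc_frac=half.gc_frac[sl],
                pop_b_freq=half.pop_b_freq[sl],
            )
            tsub = SampleIntensities("t", tumor.lrr[sl], tumor.baf[sl])
            llp, _ = forward_backward(sub, tsub, None, params)
            parts += llp
        assert ll == pytest.approx(parts, abs=1e-9)


class TestPurityEstimation:
    def _decode_free_posteriors(self, n, state_idx):
        post = np.zeros((n, N_STATES))
        post[:, state_idx] = 1.0
        return post

    def test_cnloh_band_inversion(self):
        n = 200
        tumor = SampleIntensities(
            "t", np.zeros(n), np.full(n, 0.1)
        )  # noise-free lower CNLOH band at b = 0.1
        geno = np.full(n, GENO_AB)
        post = self._decode_free_posteriors(n, I_CNLOH)
        p_hat, ok = estimate_purity(post, tumor, geno, HMMParams(p=0.5))
        assert ok
        assert p_hat == pytest.approx(0.8, abs=1e-6)

    def test_loss_band_inversion(self):
        n = 200
        tumor = SampleIntensities("t", np.zeros(n), np.full(n, 1 / 6))
        geno = np.full(n, GENO_AB)
        post = self._decode_free_posteriors(n, I_LOSS)
        p_hat, ok = estimate_purity(post, tumor, geno, HMMParams(p=0.5))
        assert ok
        assert p_hat == pytest.approx(0.8, abs=1e-6)

    def test_gain_band_inversion(self):
        n = 200
        b = 1 / (0.8 + 2)  # p = 0.8
        tumor = SampleIntensities("t", np.zeros(n), np.full(n, b))
        geno = np.full(n, GENO_AB)
        post = self._decode_free_posteriors(n, I_GAIN)
        p_hat, ok = estimate_purity(post, tumor, geno, HMMParams(p=0.5))
        assert ok
        assert p_hat == pytest.approx(0.8, abs=1e-6)

    def test_flat_sample_returns_input_with_flag(self):
        n = 200
        tumor = SampleIntensities("t", np.zeros(n), np.full(n, 0.5))
        geno = np.full(n, GENO_AB)
        post = self._decode_free_posteriors(n, I_NORMAL)
        p_hat, ok = estimate_purity(post, tumor, geno, HMMParams(p=0.61))
        assert not ok
        assert p_hat == 0.61


class TestUpdateBounds:
    def test_loss_lrr_bounds_at_full_purity(self):
        params = HMMParams(p=0.5, s0=0.0, delta_lrr=0.1)
        params = update_bounds(params, 1.0)
        low, high = params.bounds()
        assert low[I_LOSS] == pytest.approx(-1.1)
        assert high[I_LOSS] == pytest.approx(-0.9)

    def test_idempotent_when_purity_unchanged(self):
        params = HMMParams(p=0.7)
        a = update_bounds(params, 0.7)
        b = update_bounds(a, 0.7)
        np.testing.assert_allclose(a.mu_lrr, b.mu_lrr, atol=1e-12)
        np.testing.assert_allclose(a.dev_baf, b.dev_baf, atol=1e-12)

    def test_projection_onto_nearest_bound(self):
        params = HMMParams(p=0.5, s0=0.0, delta_lrr=0.1)
        params.mu_lrr[I_LOSS] = -1.5
        params = update_bounds(params, 1.0)
        assert params.mu_lrr[I_LOSS] == pytest.approx(-1.1)

    def test_band_deviation_follows_purity(self):
        params = HMMParams(p=0.3, delta_baf=0.02)
        params = update_bounds(params, 0.9)
        expected = het_band_deviation(CNState.CNLOH, 0.9)
        assert abs(params.dev_baf[I_CNLOH] - expected) <= 0.02 + 1e-12


class TestFitHMM:
    def test_noise_free_loss_chromosome_decoded_exactly(self):
        n = 120
        probes = _tiny_probes(n, spacing=500_000)
        truth = TruthProfile(
            [("1", int(probes.pos[40]), int(probes.pos[79]), CNState.LOSS)],
            purity=0.9, gc_wave_amp=0, lrr_sd=0.0, baf_sd=0.0, outlier_rate=0,
        )
        pair, tracks = simulate_pair(probes, truth, seed=1)
        params, dec = fit_hmm(pair, probes)
        np.testing.assert_array_equal(dec.states, tracks["state"])

    def test_em_loglik_non_decreasing(self, probes_small, arms):
        """Accepted EM log-likelihoods never decrease (20 seeded runs)."""
        chroms_probes = probes_small
        for seed in range(20):
            template = ["codel", "flat_normal", "astro_like", "codel_9p_cnloh"][seed % 4]
            t = expand_template(
                ScenarioTemplate(template, {"purity": 0.5 + 0.02 * seed}),
                chroms_probes, arms, seed,
            )
            pair, _ = simulate_pair(chroms_probes, t, seed=100 + seed)
            prepped, _ = preprocess_pair(pair, chroms_probes)
            _, dec = fit_hmm(prepped, chroms_probes)
            diffs = np.diff(dec.ll_trace)
            assert (diffs >= -1e-8 * np.abs(np.asarray(dec.ll_trace)[:-1])).all()

    def test_determinism(self, probes_small, arms):
        t = expand_template(
            ScenarioTemplate("codel", {"purity": 0.8}), probes_small, arms, 1
        )
        pair, _ = simulate_pair(probes_small, t, seed=2)
        prepped, _ = preprocess_pair(pair, probes_small)
        p1, d1 = fit_hmm(prepped, probes_small)
        p2, d2 = fit_hmm(prepped, probes_small)
        assert p1.p == p2.p
        assert d1.loglik == d2.loglik
        np.testing.assert_array_equal(d1.states, d2.states)

    def test_purity_recovered_on_codel(self, arms):
        probes = make_probe_set(250, seed=31, arms=arms)
        t = expand_template(
            ScenarioTemplate("codel", {"purity": 0.8}), probes, arms, 1
        )
        pair, _ = simulate_pair(probes, t, seed=32)
        prepped, _ = preprocess_pair(pair, probes)
        params, _ = fit_hmm(prepped, probes)
        assert params.p == pytest.approx(0.8, abs=0.05)

    def test_cnloh_not_called_loss(self, probes_small, arms):
        """9p CNLOH at purity >= 0.6 never decodes as LOSS (LRR separates)."""
        t = expand_template(
            ScenarioTemplate("codel_9p_cnloh", {"purity": 0.7}),
            probes_small, arms, 2,
        )
        pair, tracks = simulate_pair(probes_small, t, seed=3)
        prepped, _ = preprocess_pair(pair, probes_small)
        params, dec = fit_hmm(prepped, probes_small)
        cnloh_truth = tracks["state"] == STATE_INDEX[CNState.CNLOH]
        decoded = dec.states[cnloh_truth]
        assert not (decoded == STATE_INDEX[CNState.LOSS]).any()


class TestSegmentsFromDecoding:
    def _decoding(self, states, post_state=None):
        n = len(states)
        post = np.full((n, N_STATES), 0.01)
        for i, z in enumerate(states):
            post[i, z] = 0.95
        if post_state is not None:
            post[:, post_state] += 0.02
        return DecodingResult(
            states=np.asarray(states, dtype=np.int8),
            posteriors=post / post.sum(axis=1, keepdims=True),
            loglik=0.0, iterations=1, converged=True,
        )

    def test_short_run_merged(self):
        states = [I_NORMAL] * 50 + [I_LOSS] * 9 + [I_NORMAL] * 50
        probes = _tiny_probes(109)
        tumor = SampleIntensities("t", np.zeros(109), np.full(109, 0.5))
        segs = segments_from_decoding(self._decoding(states), probes, tumor)
        assert len(segs) == 1
        assert segs[0].state is CNState.NORMAL
        assert segs[0].n_snps == 109

    def test_ten_probe_run_retained(self):
        states = [I_NORMAL] * 50 + [I_LOSS] * 10 + [I_NORMAL] * 50
        probes = _tiny_probes(110)
        tumor = SampleIntensities("t", np.zeros(110), np.full(110, 0.5))
        segs = segments_from_decoding(self._decoding(states), probes, tumor)
        assert [s.state for s in segs] == [CNState.NORMAL, CNState.LOSS, CNState.NORMAL]
        assert segs[1].n_snps == 10

    def test_uniform_chromosome_single_segment(self):
        states = [I_LOSS] * 40
        probes = _tiny_probes(40)
        tumor = SampleIntensities("t", np.zeros(40), np.full(40, 0.5))
        segs = segments_from_decoding(self._decoding(states), probes, tumor)
        assert len(segs) == 1
        assert segs[0].start_pos == int(probes.pos[0])
        assert segs[0].end_pos == int(probes.pos[-1])

    def test_short_chromosome_flagged(self):
        states = [I_NORMAL] * 5
        probes = _tiny_probes(5)
        tumor = SampleIntensities("t", np.zeros(5), np.full(5, 0.5))
        segs = segments_from_decoding(self._decoding(states), probes, tumor)
        assert len(segs) == 1
        assert segs[0].sub_label == "short_chrom"

    def test_merge_prefers_higher_posterior_neighbor(self):
        # short GAIN run flanked by NORMAL (left) and LOSS (right); posteriors
        # over the short run favor LOSS
        states = [I_NORMAL] * 20 + [I_GAIN] * 4 + [I_LOSS] * 20
        n = len(states)
        post = np.full((n, N_STATES), 0.01)
        for i, z in enumerate(states):
            post[i, z] = 0.9
        post[20:24, I_LOSS] = 0.5
        post[20:24, I_NORMAL] = 0.2
        post /= post.sum(axis=1, keepdims=True)
        dec = DecodingResult(
            states=np.asarray(states, dtype=np.int8), posteriors=post,
            loglik=0.0, iterations=1, converged=True,
        )
        probes = _tiny_probes(n)
        tumor = SampleIntensities("t", np.zeros(n), np.full(n, 0.5))
        segs = segments_from_decoding(dec, probes, tumor)
        assert [s.state for s in segs] == [CNState.NORMAL, CNState.LOSS]
        assert segs[1].n_snps == 24
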