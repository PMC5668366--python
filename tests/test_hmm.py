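"""HMM idealization: oracle equivalences, EM behavior, histogram route."""

import itertools

import numpy as np
import pytest
from scipy.stats import norm

import smassembly as sm
from smassembly.hmm import _emission_likelihood, _viterbi, forward_loglik
from smassembly.traces import BOUND, UNBOUND

MEANS = np.array([0.15, 0.75])
SDS = np.array([0.08, 0.10])
TRANS = np.array([[0.9, 0.1], [0.2, 0.8]])
START = np.array([0.3, 0.7])


def _brute_force_loglik(x, means, sds, a, pi):
    total = 0.0
    T = len(x)
    for path in itertools.product([0, 1], repeat=T):
        p = pi[path[0]] * norm.pdf(x[0], means[path[0]], sds[path[0]])
        for t in range(1, T):
            p *= a[path[t - 1], path[t]] * norm.pdf(x[t], means[path[t]],
                                                    sds[path[t]])
        total += p
    return np.log(total)


def _brute_force_viterbi(x, means, sds, a, pi):
    best, best_lp = None, -np.inf
    logb = np.log(_emission_likelihood(x, means, sds))
    T = len(x)
    for path in itertools.product([0, 1], repeat=T):
        lp = np.log(pi[path[0]]) + logb[0, path[0]]
        for t in range(1, T):
            lp += np.log(a[path[t - 1], path[t]]) + logb[t, path[t]]
        if lp > best_lp:
            best_lp, best = lp, path
    return np.array(best), best_lp


class TestFretEfficiency:
    @pytest.mark.parametrize("donor,acceptor,expect",
                             [(500, 500, 0.5), (300, 0, 0.0), (0, 300, 1.0),
                              (300, 700, 0.7)])
    def test_values(self, donor, acceptor, expect):
        assert sm.fret_efficiency(donor, acceptor) == pytest.approx(expect)

    def test_undefined_frames_are_nan(self):
        eff = sm.fret_efficiency([0.0, -5.0], [0.0, 2.0])
        assert np.isnan(eff).all()


class TestForwardOracle:
    @pytest.mark.parametrize("length", [4, 8, 12])
    def test_forward_equals_path_sum(self, length, rng):
        x = rng.normal(0.45, 0.3, length)
        ours = forward_loglik(MEANS, SDS, TRANS, START, x)
        brute = _brute_force_loglik(x, MEANS, SDS, TRANS, START)
        assert ours == pytest.approx(brute, rel=1e-10)


class TestViterbi:
    @pytest.mark.parametrize("length", [6, 10])
    def test_matches_brute_force_argmax(self, length, rng):
        x = rng.normal(0.5, 0.3, length)
        logb = np.log(_emission_likelihood(x, MEANS, SDS))
        path = _viterbi(logb, np.log(TRANS), np.log(START))
        brute, _ = _brute_force_viterbi(x, MEANS, SDS, TRANS, START)
        assert np.array_equal(path, brute)

    def test_separable_trace_thresholds_exactly(self):
        x = np.array([0.15, 0.75, 0.75, 0.15, 0.15, 0.75] * 5)
        logb = np.log(_emission_likelihood(x, MEANS, SDS))
        path = _viterbi(logb, np.log(TRANS), np.log(START))
        assert np.array_equal(path, (x > 0.45).astype(int))

    def test_beats_random_paths(self, rng):
        x = rng.normal(0.45, 0.25, 50)
        logb = np.log(_emission_likelihood(x, MEANS, SDS))
        loga, logpi = np.log(TRANS), np.log(START)

        def lp(path):
            val = logpi[path[0]] + logb[0, path[0]]
            for t in range(1, len(path)):
                val += loga[path[t - 1], path[t]] + logb[t, path[t]]
            return val

        best = lp(_viterbi(logb, loga, logpi))
        for _ in range(300):
            assert lp(rng.integers(0, 2, 50)) <= best + 1e-9


class TestBaumWelch:
    def test_noiseless_alternation_recovers_levels(self):
        x = np.array([0.1, 0.7] * 30)
        res = sm.fit_two_state_hmm(x)
        assert res.means == pytest.approx([0.1, 0.7], abs=1e-6)
        assert (res.sds <= 1.1e-3).all()  # collapsed to the floor

    def test_loglik_monotone_nondecreasing(self, dynamic_fret_trace):
        trace, _ = dynamic_fret_trace
        res = sm.fit_two_state_hmm(trace.efficiency)
        assert np.all(np.diff(res.loglik_history) >= -1e-8)

    def test_label_order_invariance(self, dynamic_fret_trace):
        trace, _ = dynamic_fret_trace
        eff = trace.efficiency
        init_fwd = {"means": [0.1, 0.8], "sds": [0.1, 0.1],
                    "transmat": [[0.95, 0.05], [0.05, 0.95]],
                    "startprob": [0.5, 0.5]}
        init_rev = {"means": [0.8, 0.1], "sds": [0.1, 0.1],
                    "transmat": [[0.95, 0.05], [0.05, 0.95]],
                    "startprob": [0.5, 0.5]}
        a = sm.fit_two_state_hmm(eff, init=init_fwd)
        b = sm.fit_two_state_hmm(eff, init=init_rev)
        assert a.means == pytest.approx(b.means, abs=1e-6)
        assert a.mu_low < a.mu_high
        assert np.array_equal(a.viterbi(eff).states, b.viterbi(eff).states)

    def test_parameter_recovery_over_cohort(self):
        errs = []
        for i in range(50):
            p = sm.FretSimParams(k_f=0.05, k_d=0.2, e_high=0.75, e_low=0.15,
                                 seed=200 + i, initial_state="stationary-random")
            trace, _ = sm.simulate_fret_trace(p)
            res = sm.fit_two_state_hmm(trace.efficiency)
            if not res.low_evidence:
                errs.append(res.means - [0.15, 0.75])
        errs = np.abs(np.array(errs))
        assert len(errs) >= 40
        assert errs.mean(axis=0).max() < 0.03

    def test_one_level_data_flagged_low_evidence(self, rng):
        x = rng.normal(0.75, 0.08, 1000)
        res = sm.fit_two_state_hmm(x)
        assert res.low_evidence

    def test_agrees_with_hmmlearn(self, dynamic_fret_trace):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        trace, _ = dynamic_fret_trace
        eff = trace.efficiency
        ours = sm.fit_two_state_hmm(eff)
        ref = hmmlearn.GaussianHMM(n_components=2, covariance_type="diag",
                                   n_iter=500, tol=1e-6, init_params="",
                                   random_state=0)
        ref.startprob_ = np.array([0.5, 0.5])
        ref.transmat_ = np.array([[0.95, 0.05], [0.05, 0.95]])
        lo, hi = np.percentile(eff, [10, 90])
        sd = (hi - lo) / 2
        ref.means_ = np.array([[lo], [hi]])
        ref.covars_ = np.array([[sd**2], [sd**2]])
        ref.fit(eff[:, None])
        order = np.argsort(ref.means_.ravel())
        assert ours.means == pytest.approx(ref.means_.ravel()[order], abs=1e-3)
        assert np.diag(ours.transmat) == pytest.approx(
            np.diag(ref.transmat_[np.ix_(order, order)]), abs=1e-3)

    def test_requires_enough_frames(self):
        with pytest.raises(ValueError):
            sm.fit_two_state_hmm(np.ones(10))


class TestIdealizeTrace:
    def test_recovers_true_path_on_separated_trace(self):
        p = sm.FretSimParams(k_f=0.1, k_d=0.2, seed=55,
                             initial_state="stationary-random")
        trace, truth = sm.simulate_fret_trace(p)
        _, path = sm.idealize_trace(trace)
        agreement = (path.states == truth.state_path).mean()
        assert agreement > 0.97

    def test_flat_unbound_trace_yields_constant_unbound_path(self):
        p = sm.FretSimParams(k_f=0.0, k_d=0.2, initial_state="unbound", seed=56)
        trace, _ = sm.simulate_fret_trace(p)
        res, path = sm.idealize_trace(trace)
        assert res.low_evidence
        assert (path.states == UNBOUND).all()

    def test_flat_bound_trace_classified_bound(self):
        p = sm.FretSimParams(k_f=0.1, k_d=0.0, initial_state="bound", seed=57)
        trace, _ = sm.simulate_fret_trace(p)
        _, path = sm.idealize_trace(trace)
        assert (path.states == BOUND).all()

    def test_bleach_truncation(self):
        p = sm.FretSimParams(k_f=0.1, k_d=0.2, bleach_rate=0.02, seed=58)
        trace, truth = sm.simulate_fret_trace(p)
        cut = sm.truncate_bleached(trace)
        assert len(cut) < len(trace)
        assert cut.time[-1] <= truth.bleach_time + 1.0


class TestHistogramRoute:
    def test_single_level_gets_all_weight(self, rng):
        x = rng.normal(0.75, 0.05, 2000)
        fit = sm.fit_fret_histogram(x)
        assert max(fit.w_low, fit.w_high) > 0.95

    def test_balanced_mixture_weights(self, rng):
        x = np.concatenate([rng.normal(0.15, 0.08, 3000),
                            rng.normal(0.75, 0.08, 3000)])
        fit = sm.fit_fret_histogram(x, seed=1)
        se = np.sqrt(0.25 / 6000)
        assert abs(fit.w_low - 0.5) < 5 * se

    def test_stationary_cohort_weight_ratio_is_rate_ratio(self):
        k_f, k_d = 0.1, 0.2
        effs = []
        for i in range(30):
            p = sm.FretSimParams(k_f=k_f, k_d=k_d, seed=300 + i,
                                 initial_state="stationary-random")
            trace, _ = sm.simulate_fret_trace(p)
            effs.append(trace.efficiency)
        fit = sm.fit_fret_histogram(np.concatenate(effs), seed=2)
        assert sm.keq_from_histogram(fit) == pytest.approx(k_f / k_d, rel=0.15)

    @pytest.mark.parametrize("w_low,w_high,expect",
                             [(0.5, 0.5, 1.0), (0.2, 0.8, 0.25)])
    def test_keq_from_weights(self, w_low, w_high, expect):
        fit = sm.FretHistogramFit(bin_edges=np.linspace(0, 1, 11),
                                  counts=np.ones(10), w_low=w_low,
                                  w_high=w_high, means=np.array([0.15, 0.75]),
                                  sds=np.array([0.08, 0.08]))
        assert sm.keq_from_histogram(fit) == pytest.approx(expect)

    def test_empty_high_population_is_infinite(self):
        fit = sm.FretHistogramFit(bin_edges=np.linspace(0, 1, 11),
                                  counts=np.ones(10), w_low=1.0, w_high=0.0,
                                  means=np.array([0.15, 0.15]),
                                  sds=np.array([0.08, 0.08]))
        assert np.isinf(sm.keq_from_histogram(fit))

    def test_needs_enough_frames(self, rng):
        with pytest.raises(ValueError):
            sm.fit_fret_histogram(rng.normal(0.5, 0.1, 50))
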