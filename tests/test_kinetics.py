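"""Dwell extraction, cohort statistics and equilibrium constants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import smassembly as sm
from smassembly.kinetics import BOTH, COMPLETE, LEFT, RIGHT
from smassembly.traces import BOUND, UNBOUND


def path_of(labels, dt=1.0, trace_id=""):
    return sm.StatePath(states=np.array(labels, dtype=np.int8),
                        frame_interval=dt, trace_id=trace_id)


H, L = UNBOUND, BOUND


class TestMergeShortRuns:
    def test_single_frame_flip_removed(self):
        states = np.array([H, H, H, L, H, H], dtype=np.int8)
        merged = sm.merge_short_runs(states, 2)
        assert (merged == H).all()

    def test_short_run_absorbed_by_longer_neighbor(self):
        states = np.array([H] * 5 + [L] + [H] * 2, dtype=np.int8)
        merged = sm.merge_short_runs(states, 2)
        assert (merged == H).all()

    def test_long_runs_untouched(self):
        states = np.array([H, H, H, L, L, L], dtype=np.int8)
        assert np.array_equal(sm.merge_short_runs(states, 2), states)


class TestExtractDwells:
    def test_worked_enumeration(self):
        # H,H,H,L,L,L,H,H at 1 s/frame
        d = sm.extract_dwells(path_of([H, H, H, L, L, L, H, H]),
                              min_dwell_frames=2)
        assert list(d.durations) == [3.0, 3.0, 2.0]
        assert list(d.states) == [H, L, H]
        assert list(d.censoring) == [LEFT, COMPLETE, RIGHT]

    def test_single_state_path_both_censored(self):
        d = sm.extract_dwells(path_of([L] * 10))
        assert len(d) == 1 and d.censoring[0] == BOTH

    def test_complete_dwell_mean_matches_rate(self):
        durations = []
        for i in range(20):
            p = sm.FretSimParams(k_f=0.2, k_d=0.5, duration=500.0,
                                 seed=400 + i, initial_state="stationary-random")
            _, truth = sm.simulate_fret_trace(p)
            path = sm.StatePath(states=truth.state_path, frame_interval=0.05)
            d = sm.extract_dwells(path).select(BOUND)
            durations.extend(d.durations[d.censoring == COMPLETE])
        durations = np.array(durations)
        se = durations.std() / np.sqrt(durations.size)
        # mean bound dwell ~ 1/k_d, biased slightly long by frame binning
        assert abs(durations.mean() - 1 / 0.5) < 3 * se + 0.05


class TestDwellExponentialFit:
    def test_closed_form(self):
        d = sm.DwellSet(np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
                        np.array([L] * 5), np.array([COMPLETE] * 5))
        res = sm.fit_dwell_exponential(d, L, n_boot=0)
        assert res.rate == pytest.approx(5 / 15)

    def test_censored_dwells_lower_the_estimate(self):
        base = sm.DwellSet(np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
                           np.array([L] * 5), np.array([COMPLETE] * 5))
        extra = sm.DwellSet(np.array([1.0, 2.0, 3.0, 4.0, 5.0, 8.0]),
                            np.array([L] * 6),
                            np.array([COMPLETE] * 5 + [RIGHT]))
        r0 = sm.fit_dwell_exponential(base, L, n_boot=0).rate
        r1 = sm.fit_dwell_exponential(extra, L, n_boot=0).rate
        assert r1 < r0

    def test_insufficient_data_flagged(self):
        d = sm.DwellSet(np.array([1.0, 2.0]), np.array([L, L]),
                        np.array([COMPLETE, COMPLETE]))
        res = sm.fit_dwell_exponential(d, L)
        assert res.degenerate and np.isnan(res.rate)

    def test_recovers_simulated_dissociation_rate(self):
        paths = []
        for i in range(50):
            p = sm.FretSimParams(k_f=0.1, k_d=0.2, seed=500 + i,
                                 initial_state="stationary-random")
            _, truth = sm.simulate_fret_trace(p)
            paths.append(sm.StatePath(states=truth.state_path,
                                      frame_interval=0.05))
        dwells = sm.DwellSet.concat(sm.extract_dwells(p) for p in paths)
        res = sm.fit_dwell_exponential(dwells, BOUND, n_boot=500, seed=1)
        assert abs(res.rate - 0.2) < 3 * res.se + 0.01


class TestBindingFraction:
    def test_no_transitions_gives_zero(self):
        paths = [path_of([H] * 300) for _ in range(10)]
        assert sm.binding_fraction(paths, window=200).value == 0.0

    def test_every_trace_transitions_gives_one(self):
        paths = [path_of([H] * 100 + [L] * 200) for _ in range(10)]
        assert sm.binding_fraction(paths, window=250).value == 1.0

    def test_initially_bound_counts_as_binder(self):
        paths = [path_of([L] * 300), path_of([H] * 300)]
        assert sm.binding_fraction(paths, window=200).value == 0.5

    def test_short_paths_excluded_and_counted(self):
        paths = [path_of([H] * 300), path_of([H] * 50)]
        stat = sm.binding_fraction(paths, window=200)
        assert stat.n_molecules == 1 and stat.n_excluded == 1

    def test_group_sd_used_when_labelled(self):
        paths = [path_of([H] * 250) for _ in range(6)]
        paths += [path_of([H] * 50 + [L] * 200) for _ in range(6)]
        stat = sm.binding_fraction(paths, window=250,
                                   group_ids=[0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2])
        assert stat.n_groups == 3 and stat.sd > 0

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            sm.binding_fraction([], window=200)


class TestNucleationFrequency:
    def test_worked_formula(self):
        # 100 molecules, 10 binders with 2 events each, 200 s window
        binder = [H] * 10 + [L] * 50 + [H] * 50 + [L] * 110
        paths = [path_of(binder) for _ in range(10)]
        paths += [path_of([H] * 220) for _ in range(90)]
        stat = sm.apparent_nucleation_frequency(paths, window=200)
        assert stat.value == pytest.approx(2 * 0.10 * 18.0)

    def test_static_bound_traces_give_single_event_frequency(self):
        paths = [path_of([L] * 220) for _ in range(10)]
        stat = sm.apparent_nucleation_frequency(paths, window=200)
        assert stat.value == pytest.approx(1 * 1.0 * 18.0)

    def test_no_binders_flagged(self):
        paths = [path_of([H] * 220) for _ in range(10)]
        stat = sm.apparent_nucleation_frequency(paths, window=200)
        assert stat.value == 0.0 and stat.flag == "no-binders"

    @given(st.lists(st.integers(0, 5), min_size=3, max_size=12))
    @settings(deadline=None, max_examples=40)
    def test_frequency_identity_on_hand_built_paths(self, event_counts):
        # frequency == mean-events-per-molecule * 3600/window, by construction
        window = 100.0
        paths = []
        for k in event_counts:
            labels = []
            for _ in range(k):
                labels += [H] * 5 + [L] * 5
            labels += [H] * (120 - len(labels))
            paths.append(path_of(labels))
        stat = sm.apparent_nucleation_frequency(paths, window=window)
        expect = np.mean(event_counts) * 3600.0 / window
        assert stat.value == pytest.approx(expect)

    def test_invariant_to_order_and_padding(self):
        a = [path_of([H] * 100 + [L] * 150), path_of([H] * 250)]
        b = [path_of([H] * 250 + [H] * 100), path_of([H] * 100 + [L] * 250)]
        f1 = sm.apparent_nucleation_frequency(a, window=200).value
        f2 = sm.apparent_nucleation_frequency(list(reversed(b)), window=200).value
        assert f1 == pytest.approx(f2)


class TestKeq:
    @pytest.mark.parametrize("kf,kd,expect", [(0.05, 0.2, 0.25), (0.3, 0.3, 1.0)])
    def test_ratio(self, kf, kd, expect):
        assert sm.keq_from_rates(kf, kd) == pytest.approx(expect)

    def test_zero_dissociation_is_infinite(self):
        assert np.isinf(sm.keq_from_rates(0.1, 0.0))

    def test_monotone_in_decreasing_kd(self):
        kds = [0.4, 0.2, 0.1, 0.05]
        keqs = [sm.keq_from_rates(0.1, kd) for kd in kds]
        assert all(a < b for a, b in zip(keqs, keqs[1:]))


class TestLengthSeries:
    @staticmethod
    def _cohort(kf, kd, n, seed):
        paths = []
        for i in range(n):
            p = sm.FretSimParams(k_f=kf, k_d=kd, seed=seed + i,
                                 initial_state="stationary-random")
            _, truth = sm.simulate_fret_trace(p)
            paths.append(sm.StatePath(states=truth.state_path,
                                      frame_interval=0.05))
        return paths

    def test_keq_increases_as_kd_drops_across_lengths(self):
        # constant k_f, decreasing k_d with length, as for stabilizing nuclei
        conditions = [
            (15, self._cohort(0.1, 0.4, 25, 600)),
            (19, self._cohort(0.1, 0.2, 25, 700)),
            (23, self._cohort(0.1, 0.1, 25, 800)),
        ]
        rows = sm.build_length_series(conditions, n_boot=100)
        keqs = [r.keq for r in rows]
        assert keqs[0] < keqs[1] < keqs[2]

    def test_single_condition_matches_direct_calls(self):
        paths = self._cohort(0.1, 0.2, 20, 900)
        row = sm.build_length_series([(19, paths)], n_boot=100)[0]
        bf = sm.binding_fraction(paths, 200.0, n_boot=100, seed=0)
        assert row.binding_fraction == pytest.approx(bf.value)

    def test_sparse_condition_marked_not_determined(self):
        paths = [path_of([H] * 4001, dt=0.05) for _ in range(5)]
        row = sm.build_length_series([(9, paths)], n_boot=50)[0]
        assert row.not_determined
        assert np.isnan(row.k_f_app)
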