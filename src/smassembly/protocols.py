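"""End-to-end parameter-recovery studies at published RecA kinetic values.

Each protocol simulates a cohort at a generating truth taken from the
single-molecule literature on RecA E38K vs wild-type RecA filament assembly,
runs the full analysis pipeline on the synthetic traces, and returns the
recovered quantity.  They double as regression benchmarks (the recovered
value should match the generating truth within the stated statistical
tolerance) and as the computations behind ``smassembly reproduce-acceptance``.

Reference values (generating truths)
------------------------------------
* nucleation rates on (dT)60 gapped DNA: 21e-3 s^-1 (E38K), 8.0e-3 s^-1 (wt);
* per-monomer extension times: 0.75 s (E38K), 3.02 s (wt);
* (dT)19 binding fractions in 200 s: 74% (E38K), 3.0% (wt);
* (dT)19 apparent nucleation frequencies: 179 (E38K), 0.63 (wt) per molecule
  per hour.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from . import kinetics, tpm
from .hmm import idealize_trace
from .rates import bootstrap_rate
from .simulate import (
    FretSimParams,
    TpmSimParams,
    expected_event_count,
    simulate_cohort,
    simulate_tpm_trace,
    simulate_waiting_times,
)

_SEED_MASK = 0x7FFFFFFF

E38K_NUCLEATION_RATE = 21e-3          # s^-1, (dT)60 gapped DNA
WT_NUCLEATION_RATE = 8.0e-3           # s^-1
E38K_EXTENSION_S_PER_MONOMER = 0.75   # s per RecA monomer
WT_EXTENSION_S_PER_MONOMER = 3.02
DT19_E38K_BINDING_FRACTION = 0.74     # fraction of molecules, 200 s window
DT19_WT_BINDING_FRACTION = 0.030
DT19_E38K_NUCLEATION_FREQ = 179.0     # events / molecule / hour
DT19_WT_NUCLEATION_FREQ = 0.63

OBSERVATION_WINDOW = 200.0            # s
TPM_CENSOR_TIME = 600.0               # s, post-addition observation span
DEFAULT_K_D = 0.2                     # s^-1, bound-state exit rate for cohorts


def _sub_seed(seed, k):
    return (int(seed) * 1000003 + k) & _SEED_MASK


def recover_nucleation_rate(generating_rate, n_molecules=300,
                            censor_time=TPM_CENSOR_TIME, n_boot=1000, seed=0):
    """Simulate censored nucleation waiting times and refit the rate.

    Returns the :class:`~smassembly.rates.CensoredExponentialResults` of the
    censored MLE with molecule-bootstrap SE.
    """
    times, cens = simulate_waiting_times(
        generating_rate, n_molecules, censor_time, seed=_sub_seed(seed, 1)
    )
    return bootstrap_rate(times, cens, n_boot=n_boot, seed=_sub_seed(seed, 2))


def recover_extension_time(s_per_monomer, nucleation_rate, n_traces=100,
                           ssdna_nt=60, seed=0):
    """TPM extension-time recovery through the full segmentation pipeline.

    Simulates ``n_traces`` assembly traces at the generating per-monomer
    extension time, computes the 20-frame BM series, segments each trace and
    averages the recovered s/monomer over traces with a complete (nucleated
    and plateaued, non-degenerate) extension phase.

    Returns ``(mean_s_per_monomer, n_complete)``.
    """
    values = []
    for i in range(n_traces):
        p = TpmSimParams(
            nucleation_rate=nucleation_rate,
            extension_time_per_monomer=s_per_monomer,
            n_monomers_at_saturation=ssdna_nt // 3,
            seed=_sub_seed(seed, 100 + i),
        )
        trace, _ = simulate_tpm_trace(p)
        bm = tpm.compute_bm(trace)
        res = tpm.detect_assembly_phases(
            bm, addition_time=tpm.addition_time_of(trace)
        )
        if res.complete and not res.degenerate_step:
            values.append(
                tpm.extension_time_per_monomer(res.extension_duration, ssdna_nt)
            )
    if not values:
        raise RuntimeError("no trace yielded a complete extension phase")
    return float(np.mean(values)), len(values)


def calibrate_cohort(target_fraction, target_freq_per_hr=None,
                     window=OBSERVATION_WINDOW, k_d=DEFAULT_K_D):
    """Choose (k_f, active_fraction) matching cohort-level targets.

    With only ``target_fraction``: a homogeneous cohort whose probability of
    at least one binding event in the window equals the target
    (``k_f = -ln(1 - f)/window``, active_fraction 1).

    With ``target_freq_per_hr`` too: the implied events-per-binder
    ``m = freq / (fraction * 3600/window)`` fixes k_f through the renewal
    expectation ``E[N]/P(N >= 1) = m`` at the given k_d, and the active
    (binding-competent) fraction is ``target_fraction / P(N >= 1 | active)``.

    Returns ``(k_f, k_d, active_fraction)``.
    """
    if not 0 < target_fraction < 1:
        raise ValueError("target_fraction must be in (0, 1)")
    if target_freq_per_hr is None:
        k_f = -np.log(1.0 - target_fraction) / window
        return float(k_f), float(k_d), 1.0
    m = target_freq_per_hr / (target_fraction * 3600.0 / window)

    def excess(k_f):
        q = 1.0 - np.exp(-k_f * window)
        return expected_event_count(k_f, k_d, window) / q - m

    k_f = brentq(excess, 1e-8, 100.0)
    q = 1.0 - np.exp(-k_f * window)
    active = target_fraction / q
    if active > 1.0:
        raise ValueError("targets unreachable: implied active fraction > 1")
    return float(k_f), float(k_d), float(active)


def _idealize_cohort(cohort):
    return [idealize_trace(trace)[1] for trace, _ in cohort]


def recover_binding_fraction(target_fraction, n_traces=500,
                             window=OBSERVATION_WINDOW, k_d=DEFAULT_K_D, seed=0):
    """Binding-fraction recovery through the full smFRET pipeline.

    Simulates a homogeneous cohort whose expected binder fraction equals the
    target, idealizes every trace (HMM + Viterbi) and counts molecules with
    at least one binding event in the window.

    Returns the :class:`~smassembly.kinetics.CohortStat` (fraction in [0,1]).
    """
    k_f, k_d, _ = calibrate_cohort(target_fraction, window=window, k_d=k_d)
    params = FretSimParams(k_f=k_f, k_d=k_d, initial_state="unbound",
                           duration=window)
    cohort = simulate_cohort(n_traces, params, window=window,
                             seed=_sub_seed(seed, 3))
    paths = _idealize_cohort(cohort)
    return kinetics.binding_fraction(paths, window, seed=_sub_seed(seed, 4))


def recover_nucleation_frequency(target_fraction, target_freq_per_hr,
                                 n_traces=500, window=OBSERVATION_WINDOW,
                                 k_d=DEFAULT_K_D, seed=0):
    """Apparent-nucleation-frequency recovery through the full pipeline.

    The cohort is calibrated so the expected binder fraction and per-binder
    event count match the targets (binder/non-binder heterogeneity via the
    active fraction), then idealized and summarised.

    Returns ``(frequency CohortStat, binding CohortStat)``.
    """
    k_f, k_d, active = calibrate_cohort(target_fraction, target_freq_per_hr,
                                        window=window, k_d=k_d)
    params = FretSimParams(k_f=k_f, k_d=k_d, initial_state="unbound",
                           duration=window)
    cohort = simulate_cohort(n_traces, params, window=window,
                             seed=_sub_seed(seed, 5), active_fraction=active)
    paths = _idealize_cohort(cohort)
    freq = kinetics.apparent_nucleation_frequency(paths, window,
                                                  seed=_sub_seed(seed, 6))
    frac = kinetics.binding_fraction(paths, window, seed=_sub_seed(seed, 7))
    return freq, frac


def run_acceptance_suite(seed=0, n_tpm=100, n_fret=500, n_fret_rare=2000):
    """Recompute the headline recovery quantities from scratch.

    Returns a dict of short keys to ``{"value": ..., "n": ...}`` records:
    per-monomer extension times for both proteins (s/monomer), the (dT)19
    E38K binding fraction (percent) and the (dT)19 apparent nucleation
    frequencies (per molecule per hour) for both proteins.
    """
    out = {}
    v, n = recover_extension_time(
        E38K_EXTENSION_S_PER_MONOMER, E38K_NUCLEATION_RATE,
        n_traces=n_tpm, seed=_sub_seed(seed, 11),
    )
    out["extension_time_e38k"] = {"value": v, "n": n}
    v, n = recover_extension_time(
        WT_EXTENSION_S_PER_MONOMER, WT_NUCLEATION_RATE,
        n_traces=n_tpm, seed=_sub_seed(seed, 12),
    )
    out["extension_time_wt"] = {"value": v, "n": n}
    frac = recover_binding_fraction(
        DT19_E38K_BINDING_FRACTION, n_traces=n_fret, seed=_sub_seed(seed, 13)
    )
    out["binding_fraction_e38k_pct"] = {
        "value": 100.0 * frac.value, "n": frac.n_molecules,
    }
    freq, _ = recover_nucleation_frequency(
        DT19_E38K_BINDING_FRACTION, DT19_E38K_NUCLEATION_FREQ,
        n_traces=n_fret, seed=_sub_seed(seed, 14),
    )
    out["nucleation_frequency_e38k"] = {
        "value": freq.value, "n": freq.n_molecules,
    }
    freq, _ = recover_nucleation_frequency(
        DT19_WT_BINDING_FRACTION, DT19_WT_NUCLEATION_FREQ,
        n_traces=n_fret_rare, seed=_sub_seed(seed, 15),
    )
    out["nucleation_frequency_wt"] = {
        "value": freq.value, "n": freq.n_molecules,
    }
    return out
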