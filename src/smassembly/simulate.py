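"""Synthetic single-molecule trajectory generators with known ground truth.

These emulate the two assays the inference modules consume:

* TPM assembly time courses: an exponentially distributed nucleation waiting
  time at constant baseline Brownian-motion (BM) amplitude, a linear BM rise
  while RecA monomers add to the ssDNA gap, then a plateau at the saturated
  filament amplitude.  Bead centroids are drawn as isotropic Gaussians whose
  per-axis scatter tracks the target BM amplitude, plus additive centroid
  measurement noise.
* smFRET traces: a continuous-time two-state Markov (telegraph) process,
  simulated with Gillespie-style exponential holding times and binned to
  frames by majority occupancy, emitting Gaussian donor/acceptor intensities
  around the state FRET levels; optional single-step photobleaching.

Every generator is bit-reproducible under a fixed seed and returns the exact
ground truth (event times, per-frame state path, nucleation/extension
interval) so downstream estimators can be tested by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .traces import BOUND, UNBOUND, BeadTrace, FretTrace

_SEED_MASK = 0x7FFFFFFF  # keep derived seeds below 2**31


def _require(cond, msg):
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class TpmSimParams:
    """Generating parameters for one TPM assembly trace.

    ``baseline_bm``/``final_bm`` are the BM amplitudes (nm) of the bare gapped
    DNA tether and the saturated nucleoprotein filament.  Extension lasts
    ``extension_time_per_monomer * n_monomers_at_saturation`` seconds; for a
    (dT)60 gap the site size of 3 nt/monomer gives 20 monomers at saturation.

    The trace timeline mirrors the acquisition protocol: ``pre_record``
    seconds of valid bare-tether recording, then ``dead_time`` seconds of
    flow dead time flagged invalid, then the post-addition observation.  The
    nucleation clock starts at the end of the dead time.
    """

    baseline_bm: float = 30.0            # nm
    final_bm: float = 60.0               # nm
    nucleation_rate: float = 0.021       # s^-1
    extension_time_per_monomer: float = 0.75   # s per monomer
    n_monomers_at_saturation: int = 20   # ssDNA nt / 3
    frame_interval: float = 0.033        # s
    duration: float = 660.0              # s, total incl. pre-record and dead time
    centroid_noise_sd: float = 3.0       # nm, additive per-axis measurement noise
    dead_time: float = 30.0              # s, flagged invalid
    pre_record: float = 30.0             # s of valid baseline before addition
    seed: int = 0

    def __post_init__(self):
        _require(self.baseline_bm > 0, "baseline_bm must be > 0")
        _require(self.final_bm > self.baseline_bm, "final_bm must exceed baseline_bm")
        _require(self.nucleation_rate >= 0, "nucleation_rate must be >= 0")
        _require(self.extension_time_per_monomer > 0,
                 "extension_time_per_monomer must be > 0")
        _require(self.n_monomers_at_saturation >= 1,
                 "n_monomers_at_saturation must be >= 1")
        _require(self.frame_interval > 0, "frame_interval must be > 0")
        _require(self.duration > self.pre_record + self.dead_time,
                 "duration must exceed pre_record + dead_time")
        _require(self.centroid_noise_sd >= 0, "centroid_noise_sd must be >= 0")
        _require(self.dead_time >= 0, "dead_time must be >= 0")
        _require(self.pre_record >= 0, "pre_record must be >= 0")

    @property
    def extension_duration(self):
        return self.extension_time_per_monomer * self.n_monomers_at_saturation


@dataclass(frozen=True)
class FretSimParams:
    """Generating parameters for one smFRET trace.

    ``k_f`` is the unbound->bound (nucleation-cluster formation) rate, ``k_d``
    the bound->unbound (dissociation) rate, both in s^-1.  ``e_high`` is the
    bare-DNA FRET level, ``e_low`` the protein-bound level.  Intensities are
    ``(1-E)*total_intensity`` (donor) and ``E*total_intensity`` (acceptor)
    plus independent Gaussian channel noise.  ``bleach_rate`` 0 disables
    photobleaching (at 200 s observation most fluorophores survive).
    """

    k_f: float = 0.1                 # s^-1, unbound -> bound
    k_d: float = 0.2                 # s^-1, bound -> unbound
    e_high: float = 0.75             # unbound FRET level
    e_low: float = 0.15              # bound FRET level
    total_intensity: float = 1000.0  # counts/frame
    intensity_noise_sd: float = 100.0  # counts/frame per channel
    frame_interval: float = 0.05     # s
    duration: float = 200.0          # s
    bleach_rate: float = 0.0         # s^-1, 0 disables
    initial_state: str = "unbound"   # unbound | bound | stationary-random
    seed: int = 0

    def __post_init__(self):
        _require(0.0 <= self.e_low < self.e_high <= 1.0,
                 "need 0 <= e_low < e_high <= 1")
        _require(self.k_f >= 0 and self.k_d >= 0, "rates must be >= 0")
        _require(self.total_intensity > 0, "total_intensity must be > 0")
        _require(self.intensity_noise_sd >= 0, "intensity_noise_sd must be >= 0")
        _require(self.frame_interval > 0 and self.duration > 0,
                 "frame_interval and duration must be > 0")
        n = self.duration / self.frame_interval
        _require(abs(n - round(n)) < 1e-9,
                 "duration must be an integer number of frames")
        _require(self.bleach_rate >= 0, "bleach_rate must be >= 0")
        _require(self.initial_state in ("unbound", "bound", "stationary-random"),
                 "initial_state must be unbound|bound|stationary-random")

    @property
    def n_frames(self):
        return int(round(self.duration / self.frame_interval))


@dataclass
class GroundTruth:
    """Exact generating record for one simulated trace."""

    params: object
    state_path: np.ndarray = None        # per-frame true state (FRET)
    event_times: np.ndarray = None       # continuous-time transition times, s
    initial_state: int = None            # continuous-time state at t=0 (FRET)
    nucleation_time: float = None        # s after protein addition (TPM)
    extension_interval: tuple = None     # absolute (start, end) s (TPM)
    bleach_time: float = None            # s, None if no bleach

    def __post_init__(self):
        if self.event_times is not None:
            self.event_times = np.asarray(self.event_times, dtype=float)
            if self.event_times.size > 1 and np.any(np.diff(self.event_times) <= 0):
                raise ValueError("event times must be strictly increasing")


def simulate_waiting_times(rate, n, censor_time, seed=0):
    """Draw exponential waiting times right-censored at ``censor_time``.

    Returns ``(times, censored)`` where censored draws are reported at the
    censoring bound with flag True.  ``censor_time`` may be ``numpy.inf``.
    """
    _require(rate > 0, "rate must be > 0")
    _require(n >= 1, "n must be >= 1")
    _require(censor_time > 0, "censor_time must be > 0")
    rng = np.random.default_rng(seed)
    raw = rng.exponential(1.0 / rate, size=int(n))
    censored = raw > censor_time
    times = np.where(censored, censor_time, raw)
    return times, censored


def simulate_tpm_trace(params: TpmSimParams):
    """Simulate one TPM assembly trace.

    Returns ``(BeadTrace, GroundTruth)``.  The nucleation waiting time is
    exponential with ``params.nucleation_rate``, measured from the end of the
    dead time; the BM target then rises linearly to ``final_bm`` over the
    extension interval.  Centroids are N(0, sigma_axis^2) per axis with
    sigma_axis chosen so the combined-axis amplitude sqrt(var_x + var_y)
    equals the target BM, plus additive centroid noise.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration / p.frame_interval))
    time = np.arange(n) * p.frame_interval
    t_add = p.pre_record + p.dead_time    # absolute protein-addition time
    if p.nucleation_rate > 0:
        t_nuc = rng.exponential(1.0 / p.nucleation_rate)
    else:
        t_nuc = np.inf
    ext = p.extension_duration
    t0 = t_add + t_nuc                    # absolute extension start
    t1 = t0 + ext                         # absolute extension end

    target = np.full(n, p.baseline_bm)
    if np.isfinite(t0):
        ramp = (time >= t0) & (time < t1)
        target[ramp] = p.baseline_bm + (p.final_bm - p.baseline_bm) * (
            (time[ramp] - t0) / ext
        )
        target[time >= t1] = p.final_bm
    sigma_axis = np.sqrt(target**2 / 2.0 + p.centroid_noise_sd**2)
    x = rng.normal(0.0, sigma_axis)
    y = rng.normal(0.0, sigma_axis)
    valid = (time < p.pre_record) | (time >= t_add)

    trace = BeadTrace(time=time, x=x, y=y, valid=valid)
    truth = GroundTruth(
        params=p,
        nucleation_time=float(t_nuc),
        extension_interval=(float(t0), float(t1)),
    )
    return trace, truth


def _telegraph_events(rng, k_f, k_d, duration, initial_state):
    """Gillespie draw of the continuous-time two-state path.

    Returns (state0, event_times) with event_times strictly inside
    [0, duration); the state flips at each event time.
    """
    if initial_state == "unbound":
        state = UNBOUND
    elif initial_state == "bound":
        state = BOUND
    else:  # stationary-random
        p_bound = k_f / (k_f + k_d) if (k_f + k_d) > 0 else 0.0
        state = BOUND if rng.random() < p_bound else UNBOUND
    state0 = state
    events = []
    t = 0.0
    while True:
        rate = k_f if state == UNBOUND else k_d
        if rate <= 0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            break
        events.append(t)
        state = BOUND if state == UNBOUND else UNBOUND
    return state0, np.asarray(events)


def _bin_majority(state0, events, n_frames, dt):
    """Bin a continuous-time two-state path to frames by majority occupancy."""
    # piecewise-constant bound indicator; cumulative bound time is piecewise
    # linear in t, so np.interp at frame edges is exact
    breaks = np.concatenate(([0.0], events, [n_frames * dt]))
    seg_state = np.empty(breaks.size - 1, dtype=np.int8)
    s = state0
    for i in range(seg_state.size):
        seg_state[i] = s
        s = BOUND if s == UNBOUND else UNBOUND
    seg_bound = (seg_state == BOUND).astype(float)
    cum = np.concatenate(([0.0], np.cumsum(seg_bound * np.diff(breaks))))
    edges = np.arange(n_frames + 1) * dt
    bound_frac = np.diff(np.interp(edges, breaks, cum)) / dt
    return np.where(bound_frac > 0.5, BOUND, UNBOUND).astype(np.int8)


def simulate_fret_trace(params: FretSimParams):
    """Simulate one smFRET trace; returns ``(FretTrace, GroundTruth)``.

    The telegraph path is simulated in continuous time and binned to frames
    by majority occupancy, which avoids discretization bias at 50 ms frames.
    If photobleaching occurs, both channels drop to background (pure noise)
    from the bleach frame on and the bleach time is recorded.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = p.n_frames
    dt = p.frame_interval
    state0, events = _telegraph_events(rng, p.k_f, p.k_d, p.duration, p.initial_state)
    path = _bin_majority(state0, events, n, dt)

    e_state = np.where(path == BOUND, p.e_low, p.e_high)
    donor = (1.0 - e_state) * p.total_intensity + rng.normal(0, p.intensity_noise_sd, n)
    acceptor = e_state * p.total_intensity + rng.normal(0, p.intensity_noise_sd, n)

    bleach_time = None
    if p.bleach_rate > 0:
        t_bleach = rng.exponential(1.0 / p.bleach_rate)
        if t_bleach < p.duration:
            bleach_time = float(t_bleach)
            dark = np.arange(n) * dt >= t_bleach
            donor[dark] = rng.normal(0, p.intensity_noise_sd, dark.sum())
            acceptor[dark] = rng.normal(0, p.intensity_noise_sd, dark.sum())

    time = np.arange(n) * dt
    trace = FretTrace(time=time, donor=donor, acceptor=acceptor)
    truth = GroundTruth(
        params=p, state_path=path, event_times=events, initial_state=int(state0),
        bleach_time=bleach_time,
    )
    return trace, truth


def true_dwells(truth: GroundTruth):
    """Complete (uncensored) continuous-time dwell durations from ground truth.

    Returns ``(bound_dwells, unbound_dwells)``, excluding the left-censored
    first and right-censored last holding intervals.
    """
    events = truth.event_times
    if events is None or events.size < 2:
        return np.empty(0), np.empty(0)
    durs = np.diff(events)
    s = BOUND if truth.initial_state == UNBOUND else UNBOUND  # state after 1st event
    states = np.empty(durs.size, dtype=np.int8)
    for i in range(durs.size):
        states[i] = s
        s = BOUND if s == UNBOUND else UNBOUND
    return durs[states == BOUND], durs[states == UNBOUND]


def simulate_cohort(n_molecules, params: FretSimParams, window=None, seed=0,
                    active_fraction=1.0):
    """Simulate an independent cohort of smFRET molecules.

    Per-trace seeds are derived from the master seed as ``seed ^ index``.
    ``active_fraction`` < 1 makes a deterministic-in-expectation subset of
    molecules inert (k_f = 0), emulating the molecule-to-molecule
    heterogeneity in whether any binding event occurs within the observation
    window; inert molecules never leave the unbound state.  With
    ``active_fraction = 1`` and ``initial_state='unbound'`` the expected
    fraction of molecules with at least one binding event in ``window``
    seconds is ``1 - exp(-k_f * window)``.

    Returns a list of ``(FretTrace, GroundTruth)`` pairs.
    """
    _require(n_molecules >= 1, "n_molecules must be >= 1")
    _require(0.0 <= active_fraction <= 1.0, "active_fraction must be in [0, 1]")
    if window is not None:
        _require(window <= params.duration, "window cannot exceed trace duration")
    master = np.random.default_rng(seed)
    active = master.random(n_molecules) < active_fraction
    inert = replace(params, k_f=0.0, initial_state="unbound")
    out = []
    for i in range(n_molecules):
        p_i = replace(params if active[i] else inert, seed=(int(seed) ^ i) & _SEED_MASK)
        out.append(simulate_fret_trace(p_i))
    return out


def expected_event_count(k_f, k_d, window):
    """Expected number of unbound->bound transitions in [0, window].

    Renewal result for the telegraph process started unbound:
    ``E[N] = kf*kd*T/(kf+kd) + (kf/(kf+kd))^2 * (1 - exp(-(kf+kd)*T))``.
    Reduces to ``1 - exp(-kf*T)`` as k_d -> 0.
    """
    s = k_f + k_d
    if s <= 0:
        return 0.0
    return k_f * k_d * window / s + (k_f / s) ** 2 * (1.0 - math.exp(-s * window))
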