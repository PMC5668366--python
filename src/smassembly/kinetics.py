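"""Nucleation-cluster kinetics from idealized state paths.

From each molecule's two-state idealization this module extracts censored
dwell times, fits single-exponential dwell distributions (censored MLE with
bootstrap SE) to obtain the apparent nucleation-cluster formation rate
k_f_app (unbound dwells) and dissociation rate k_d (bound dwells), and
computes the cohort statistics used to compare proteins across ssDNA
lengths:

* binding fraction — fraction of molecules showing at least one binding
  event within the observation window (default 200 s);
* apparent nucleation frequency — mean binding events per binder in the
  window, times the binding fraction, rescaled to per molecule per hour
  (equivalently: total events per molecule x 3600/window);
* association equilibrium constant K_eq = k_f_app / k_d.

Each high-to-low-FRET (unbound->bound) transition counts as one nucleation
event; a molecule already bound at the first frame (binding within the flow
dead time) counts as a binder with one event, its initial bound dwell being
left-censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rates import CensoredExponential, CensoredExponentialResults
from .traces import BOUND, UNBOUND, StatePath

COMPLETE = "complete"
LEFT = "left-censored"
RIGHT = "right-censored"
BOTH = "both-censored"


def _rle(states):
    """Run-length encode a 1-D label array -> (values, lengths)."""
    states = np.asarray(states)
    if states.size == 0:
        return np.empty(0, dtype=states.dtype), np.empty(0, dtype=int)
    change = np.flatnonzero(states[1:] != states[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [states.size]))
    return states[starts], ends - starts


def merge_short_runs(states, min_frames=2):
    """Merge runs shorter than ``min_frames`` into their longer neighbor.

    Suppresses single-frame noise flips in Viterbi paths.  The shortest
    offending run is absorbed first (ties: earliest); interior runs go to the
    longer neighbor (ties: the preceding one), edge runs to their only
    neighbor.  Returns a new label array of the same length.
    """
    vals, lens = _rle(states)
    while vals.size > 1:
        short = np.flatnonzero(lens < min_frames)
        if short.size == 0:
            break
        k = short[np.argmin(lens[short])]
        if k == 0:
            nb = 1
        elif k == vals.size - 1:
            nb = k - 1
        else:
            nb = k - 1 if lens[k - 1] >= lens[k + 1] else k + 1
        vals[k] = vals[nb]
        keep = np.concatenate(([True], vals[1:] != vals[:-1]))
        merged_lens = np.add.reduceat(lens, np.flatnonzero(keep))
        vals = vals[keep]
        lens = merged_lens
    return np.repeat(vals, lens)


@dataclass
class DwellSet:
    """State-labelled dwell durations with censoring flags."""

    durations: np.ndarray          # seconds
    states: np.ndarray             # BOUND / UNBOUND per dwell
    censoring: np.ndarray          # COMPLETE/LEFT/RIGHT/BOTH per dwell
    trace_ids: np.ndarray = None

    def __post_init__(self):
        self.durations = np.asarray(self.durations, dtype=float)
        self.states = np.asarray(self.states, dtype=np.int8)
        self.censoring = np.asarray(self.censoring, dtype=object)
        n = self.durations.size
        if self.trace_ids is None:
            self.trace_ids = np.array([""] * n, dtype=object)
        self.trace_ids = np.asarray(self.trace_ids, dtype=object)
        if not (self.states.size == self.censoring.size == self.trace_ids.size == n):
            raise ValueError("all DwellSet arrays must have equal length")

    def __len__(self):
        return self.durations.size

    def select(self, state):
        m = self.states == state
        return DwellSet(self.durations[m], self.states[m], self.censoring[m],
                        self.trace_ids[m])

    @staticmethod
    def concat(dwellsets):
        sets = list(dwellsets)
        if not sets:
            return DwellSet(np.empty(0), np.empty(0, np.int8),
                            np.empty(0, object), np.empty(0, object))
        return DwellSet(
            np.concatenate([d.durations for d in sets]),
            np.concatenate([d.states for d in sets]),
            np.concatenate([d.censoring for d in sets]),
            np.concatenate([d.trace_ids for d in sets]),
        )


def extract_dwells(path: StatePath, frame_interval=None, min_dwell_frames=2) -> DwellSet:
    """Convert an idealized path to censored dwell durations.

    Runs shorter than ``min_dwell_frames`` (default 2 frames, 100 ms at 50 ms
    resolution) are merged into their longer neighbor before conversion.  The
    first dwell of a trace is left-censored, the last right-censored; a
    single-run trace yields one both-censored dwell.
    """
    dt = frame_interval if frame_interval is not None else path.frame_interval
    states = merge_short_runs(path.states, min_dwell_frames)
    vals, lens = _rle(states)
    durations = lens * dt
    n = vals.size
    cens = np.array([COMPLETE] * n, dtype=object)
    if n == 1:
        cens[0] = BOTH
    else:
        cens[0] = LEFT
        cens[-1] = RIGHT
    ids = np.array([path.trace_id] * n, dtype=object)
    return DwellSet(durations, vals, cens, ids)


def fit_dwell_exponential(dwells: DwellSet, state=None, include_censored=True,
                          n_boot=1000, seed=0) -> CensoredExponentialResults:
    """Censored-exponential MLE of the exit rate from one state.

    ``state=UNBOUND`` dwells yield k_f_app, ``state=BOUND`` dwells k_d.
    Complete dwells are events; left-/right-censored dwells enter the
    denominator only (``include_censored``); both-censored single-dwell
    traces are excluded entirely.  Requires at least 5 complete dwells,
    otherwise the returned estimate is flagged degenerate with rate NaN.
    """
    d = dwells if state is None else dwells.select(state)
    complete = d.censoring == COMPLETE
    partial = (d.censoring == LEFT) | (d.censoring == RIGHT)
    n_complete = int(complete.sum())
    if n_complete < 5:
        return CensoredExponentialResults(
            rate=np.nan, se=np.nan, n_total=len(d), n_events=n_complete,
            n_boot=0, seed=seed, degenerate=True,
        )
    if include_censored:
        keep = complete | partial
    else:
        keep = complete
    model = CensoredExponential(d.durations[keep], ~complete[keep])
    return model.fit(n_boot=n_boot, seed=seed)


def count_nucleation_events(path: StatePath, window=200.0):
    """Number of nucleation (unbound->bound) events within ``window`` seconds.

    Short runs are merged first (same smoothing as dwell extraction).  A path
    whose first frame is already bound counts one event (binding occurred
    within the flow dead time).
    """
    n_frames = min(int(round(window / path.frame_interval)), len(path))
    states = merge_short_runs(path.states[:n_frames])
    if states.size == 0:
        return 0
    events = int(np.sum((states[:-1] == UNBOUND) & (states[1:] == BOUND)))
    if states[0] == BOUND:
        events += 1
    return events


def _group_or_bootstrap_sd(values_per_trace, statistic, group_ids, n_boot, seed):
    """SD of a cohort statistic: across experiment groups when labelled
    (>= 2 groups), else by bootstrap over molecules."""
    values_per_trace = np.asarray(values_per_trace, dtype=float)
    if group_ids is not None:
        group_ids = np.asarray(group_ids)
        groups = np.unique(group_ids)
        if groups.size >= 2:
            stats = [statistic(values_per_trace[group_ids == g]) for g in groups]
            return float(np.std(stats, ddof=1)), int(groups.size)
    rng = np.random.default_rng(seed)
    n = values_per_trace.size
    idx = rng.integers(0, n, size=(n_boot, n))
    stats = np.apply_along_axis(statistic, 1, values_per_trace[idx])
    return float(np.std(stats, ddof=1)), 0


@dataclass
class CohortStat:
    """A cohort-level statistic with its spread and bookkeeping."""

    value: float
    sd: float
    n_molecules: int
    n_groups: int = 0
    n_excluded: int = 0
    flag: str = ""


def binding_fraction(paths, window=200.0, group_ids=None, n_boot=1000,
                     seed=0) -> CohortStat:
    """Fraction of molecules with >= 1 binding event within the window.

    Paths shorter than the window are excluded from the denominator and
    reported in ``n_excluded``.  The SD is taken across experiment groups
    when ``group_ids`` labels >= 2 groups, else by bootstrap over molecules.
    """
    paths = list(paths)
    if not paths:
        raise ValueError("empty cohort")
    ok = [p.duration >= window - 0.5 * p.frame_interval for p in paths]
    kept = [p for p, o in zip(paths, ok) if o]
    n_excluded = len(paths) - len(kept)
    if not kept:
        raise ValueError("no path covers the observation window")
    if group_ids is not None:
        group_ids = np.asarray(group_ids)[np.asarray(ok)]
    binder = np.array(
        [count_nucleation_events(p, window) > 0 for p in kept], dtype=float
    )
    sd, n_groups = _group_or_bootstrap_sd(binder, np.mean, group_ids, n_boot, seed)
    return CohortStat(
        value=float(binder.mean()), sd=sd, n_molecules=len(kept),
        n_groups=n_groups, n_excluded=n_excluded,
    )


def apparent_nucleation_frequency(paths, window=200.0, group_ids=None,
                                  n_boot=1000, seed=0) -> CohortStat:
    """Apparent nucleation frequency in events per molecule per hour.

    Defined as (mean events per binder within the window) x (binding
    fraction) x (3600/window), which telescopes to
    (total events / molecules) x 3600/window.  Zero binders yields 0 with a
    flag.
    """
    paths = list(paths)
    if not paths:
        raise ValueError("empty cohort")
    ok = [p.duration >= window - 0.5 * p.frame_interval for p in paths]
    kept = [p for p, o in zip(paths, ok) if o]
    n_excluded = len(paths) - len(kept)
    if not kept:
        raise ValueError("no path covers the observation window")
    if group_ids is not None:
        group_ids = np.asarray(group_ids)[np.asarray(ok)]
    events = np.array([count_nucleation_events(p, window) for p in kept], dtype=float)
    scale = 3600.0 / window

    def stat(ev):
        return ev.mean() * scale

    flag = "" if (events > 0).any() else "no-binders"
    sd, n_groups = _group_or_bootstrap_sd(events, stat, group_ids, n_boot, seed)
    return CohortStat(
        value=float(stat(events)), sd=sd, n_molecules=len(kept),
        n_groups=n_groups, n_excluded=n_excluded, flag=flag,
    )


def keq_from_rates(k_f_app, k_d):
    """Association equilibrium constant K_eq = k_f_app / k_d.

    Returns ``inf`` for k_d = 0; NaN inputs propagate.
    """
    if k_d == 0:
        return np.inf
    return k_f_app / k_d


@dataclass
class NucleationSummary:
    """Per-ssDNA-length cohort summary (one table row).

    Rates are NaN (reported N.D.) when fewer than 5 complete dwells of the
    relevant state were available.
    """

    ssdna_nt: int
    binding_fraction: float
    binding_fraction_sd: float
    nucleation_frequency: float      # per molecule per hour
    nucleation_frequency_sd: float
    k_f_app: float                   # s^-1
    k_f_app_se: float
    k_d: float                       # s^-1
    k_d_se: float
    keq: float
    n_molecules: int
    window: float

    @property
    def not_determined(self):
        return not (np.isfinite(self.k_f_app) and np.isfinite(self.k_d))

    def as_dict(self):
        return {
            "ssdna_nt": self.ssdna_nt,
            "binding_fraction_pct": 100.0 * self.binding_fraction,
            "binding_fraction_pct_sd": 100.0 * self.binding_fraction_sd,
            "nucleation_frequency_per_hr": self.nucleation_frequency,
            "nucleation_frequency_per_hr_sd": self.nucleation_frequency_sd,
            "k_f_app_per_s": self.k_f_app,
            "k_f_app_se_per_s": self.k_f_app_se,
            "k_d_per_s": self.k_d,
            "k_d_se_per_s": self.k_d_se,
            "keq": self.keq,
            "n_molecules": self.n_molecules,
            "window_s": self.window,
        }


def summarize_condition(ssdna_nt, paths, window=200.0, group_ids=None,
                        min_dwell_frames=2, n_boot=1000, seed=0) -> NucleationSummary:
    """Full cohort summary for one ssDNA length.

    Dwells are pooled across the condition's molecules; k_f_app comes from
    unbound dwells, k_d from bound dwells.
    """
    paths = list(paths)
    bf = binding_fraction(paths, window, group_ids, n_boot, seed)
    freq = apparent_nucleation_frequency(paths, window, group_ids, n_boot, seed)
    dwells = DwellSet.concat(
        extract_dwells(p, min_dwell_frames=min_dwell_frames) for p in paths
    )
    kf = fit_dwell_exponential(dwells, UNBOUND, n_boot=n_boot, seed=seed)
    kd = fit_dwell_exponential(dwells, BOUND, n_boot=n_boot, seed=seed + 1)
    if kf.degenerate or kd.degenerate or kd.rate == 0:
        keq = np.nan
    else:
        keq = keq_from_rates(kf.rate, kd.rate)
    return NucleationSummary(
        ssdna_nt=int(ssdna_nt),
        binding_fraction=bf.value,
        binding_fraction_sd=bf.sd,
        nucleation_frequency=freq.value,
        nucleation_frequency_sd=freq.sd,
        k_f_app=kf.rate,
        k_f_app_se=kf.se,
        k_d=kd.rate,
        k_d_se=kd.se,
        keq=keq,
        n_molecules=bf.n_molecules,
        window=window,
    )


def build_length_series(conditions, window=200.0, min_dwell_frames=2,
                        n_boot=1000, seed=0):
    """Summaries for a series of ssDNA-length conditions.

    ``conditions``: iterable of ``(ssdna_nt, paths)`` or ``(ssdna_nt, paths,
    group_ids)``.  Returns a list of :class:`NucleationSummary` sorted by
    length; conditions with too few complete dwells carry NaN (N.D.) rates.
    """
    rows = []
    for item in conditions:
        if len(item) == 3:
            nt, paths, gids = item
        else:
            nt, paths = item
            gids = None
        rows.append(
            summarize_condition(nt, paths, window, gids, min_dwell_frames,
                                n_boot, seed)
        )
    return sorted(rows, key=lambda r: r.ssdna_nt)
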