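"""TPM trace analysis: BM amplitude, assembly-phase segmentation, rates.

The Brownian-motion (BM) amplitude of a tethered bead is the standard
deviation of its centroid positions over a 20-frame sliding window; RecA
assembly on the ssDNA gap lengthens the tether and raises the BM.  An
assembly time course has three regions: (i) a baseline waiting period until a
stable nucleus forms (the nucleation time), (ii) a continuous BM rise while
monomers add (the extension phase), and (iii) a plateau at the saturated
filament amplitude.  Dividing the extension duration by the number of RecA
monomers at saturation (ssDNA nt / 3) gives the per-monomer extension time.

Nucleation times across many tethers are exponential; tethers that never
nucleate within the observation span enter the rate fit as right-censored
waiting times (see :mod:`smassembly.rates`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rates import CensoredExponential, bootstrap_rate, nucleation_rate_mle  # noqa: F401
from .traces import BeadTrace


@dataclass
class BmSeries:
    """Windowed BM-amplitude series; timestamps are window centers.

    ``window`` records how many frames each value pools; consecutive values
    (one-frame slide) share ``window - 1`` frames and are strongly correlated,
    which segmentation must account for.
    """

    time: np.ndarray
    bm: np.ndarray
    window: int = 20

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.bm = np.asarray(self.bm, dtype=float)
        if self.time.size != self.bm.size:
            raise ValueError("time and bm must have equal length")
        if np.any(self.bm < 0):
            raise ValueError("bm must be non-negative")

    def __len__(self):
        return self.time.size

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.time, self.bm, **kwargs)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("BM amplitude (nm)")
        return ax


@dataclass
class AssemblyResult:
    """Segmentation of one assembly time course.

    ``nucleation_time`` is measured from protein addition (end of dead time).
    ``right_censored`` marks tethers with no BM rise within the observation
    span (their nucleation_time is the observed span, a lower bound);
    ``incomplete_extension`` marks rises that had not plateaued by trace end.
    """

    nucleation_time: float
    extension_duration: float
    bm_increment: float
    baseline_mean: float
    baseline_sd: float
    plateau_bm: float
    right_censored: bool = False
    incomplete_extension: bool = False
    degenerate_step: bool = False

    @property
    def complete(self):
        return not (self.right_censored or self.incomplete_extension)


def compute_bm(trace: BeadTrace, window: int = 20) -> BmSeries:
    """Sliding-window BM amplitude of a bead trace.

    BM is the combined-axis centroid scatter ``sqrt(var(x) + var(y))`` (sample
    variances about the window mean) over ``window`` consecutive frames; the
    window advances one frame and the output timestamp is the window center.
    Windows containing any invalid frame are dropped.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    n = len(trace)
    if int(trace.valid.sum()) < window:
        raise ValueError("trace has fewer valid frames than the window")
    if n < window:
        raise ValueError("trace shorter than window")

    sw = np.lib.stride_tricks.sliding_window_view
    xw = sw(trace.x, window)
    yw = sw(trace.y, window)
    var = xw.var(axis=1, ddof=1) + yw.var(axis=1, ddof=1)
    bm = np.sqrt(var)
    tw = sw(trace.time, window).mean(axis=1)
    ok = sw(trace.valid, window).all(axis=1)
    return BmSeries(time=tw[ok], bm=bm[ok], window=window)


def addition_time_of(trace: BeadTrace) -> float:
    """Protein-addition time inferred from the invalid (dead-time) frames.

    Returns the time of the first valid frame after the last invalid one, or
    the trace start when no frames are flagged.
    """
    if trace.valid.all():
        return float(trace.time[0])
    last_invalid = int(np.flatnonzero(~trace.valid)[-1])
    if last_invalid + 1 < len(trace):
        return float(trace.time[last_invalid + 1])
    return float(trace.time[-1])


def _first_sustained_crossing(values, threshold, min_run):
    """Index of the first value opening a run of >= min_run values > threshold."""
    above = values > threshold
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= min_run:
            return i - min_run + 1
    return None


def detect_assembly_phases(
    bm: BmSeries,
    baseline=None,
    rise_k: float = 3.0,
    plateau_frac: float = 0.9,
    min_run: int = 5,
    addition_time: float = None,
    baseline_span: float = 20.0,
    plateau_tail_frac: float = 0.1,
    refine: bool = True,
) -> AssemblyResult:
    """Segment a BM series into nucleation / extension / plateau regions.

    Nucleation is the first time BM exceeds ``baseline_mean + rise_k *
    baseline_sd`` for at least ``min_run`` consecutive *independent* windows,
    measured from ``addition_time`` (protein addition; defaults to the first
    window time).  Because the sliding window advances one frame, consecutive
    BM values share all but one frame, so the persistence run is counted in
    spans of ``bm.window`` values (min_run spans = ``min_run * bm.window``
    consecutive values above threshold); a single noise excursion decays
    within one span and cannot fire it.
    The plateau level is the mean of the final ``plateau_tail_frac`` of
    windows and the extension ends at the first window reaching
    ``baseline + plateau_frac * (plateau - baseline)``.

    With ``refine=True`` (default) the threshold crossings only initialize a
    local least-squares fit of the three-segment model (flat baseline, linear
    ramp between breakpoints t0/t1, flat plateau) and the phase boundaries
    are the fitted breakpoints; this removes the threshold-induced bias of
    the raw crossings (the rise crossing fires well into the ramp, the
    plateau crossing before its end).

    ``baseline`` may be a ``(mean, sd)`` tuple; otherwise it is estimated
    from pre-addition windows if any exist, else robustly (median/MAD) from
    the first ``baseline_span`` seconds after addition.
    """
    if len(bm) < min_run + 2:
        raise ValueError("BM series too short to segment")
    t = bm.time
    v = bm.bm
    if addition_time is None:
        addition_time = float(t[0])

    if baseline is None:
        pre = v[t < addition_time]
        if pre.size >= 5:
            base_mean, base_sd = float(pre.mean()), float(pre.std(ddof=1))
        else:
            early = v[(t >= addition_time) & (t <= addition_time + baseline_span)]
            if early.size < 5:
                raise ValueError("no frames available to estimate the baseline")
            base_mean = float(np.median(early))
            base_sd = float(1.4826 * np.median(np.abs(early - base_mean)))
            if base_sd == 0.0:
                base_sd = float(early.std(ddof=1))
    else:
        base_mean, base_sd = float(baseline[0]), float(baseline[1])

    post = t >= addition_time
    tp, vp = t[post], v[post]
    if tp.size < min_run + 2:
        raise ValueError("no post-addition windows to segment")
    span = float(tp[-1] - addition_time)

    thr = base_mean + rise_k * base_sd
    run_len = max(min_run, 1) * max(bm.window, 1)
    i_rise = _first_sustained_crossing(vp, thr, min(run_len, max(vp.size - 1, 1)))
    if i_rise is None:
        return AssemblyResult(
            nucleation_time=span,
            extension_duration=0.0,
            bm_increment=0.0,
            baseline_mean=base_mean,
            baseline_sd=base_sd,
            plateau_bm=float(np.median(vp)),
            right_censored=True,
        )

    n_tail = max(int(round(plateau_tail_frac * vp.size)), 5)
    plateau = float(vp[-n_tail:].mean())
    level_end = base_mean + plateau_frac * (plateau - base_mean)
    # the plateau crossing must be sustained too, for the same reason
    rel = _first_sustained_crossing(
        vp[i_rise:], level_end, min(run_len, max(vp.size - i_rise - 1, 1))
    )
    incomplete = rel is None
    i_end = (i_rise + rel) if not incomplete else (vp.size - 1)
    # a rise reaching its "plateau" only inside the tail that defined the
    # plateau level has not demonstrably saturated
    if not incomplete and i_end >= vp.size - n_tail:
        incomplete = True

    t_rise = float(tp[i_rise])
    t_end = float(tp[i_end])
    degenerate = i_end <= i_rise

    if refine and not incomplete and not degenerate:
        t_rise, t_end = _fit_ramp_breakpoints(
            tp, vp, base_mean, plateau, t_rise, t_end, addition_time
        )

    nucleation_time = max(t_rise - addition_time, 0.0)
    extension_duration = max(t_end - t_rise, 0.0)
    return AssemblyResult(
        nucleation_time=nucleation_time,
        extension_duration=extension_duration,
        bm_increment=plateau - base_mean,
        baseline_mean=base_mean,
        baseline_sd=base_sd,
        plateau_bm=plateau,
        incomplete_extension=incomplete,
        degenerate_step=degenerate,
    )


def _fit_ramp_breakpoints(tp, vp, base_mean, plateau, t_rise, t_end,
                          addition_time):
    """Local least-squares fit of the baseline-ramp-plateau breakpoints.

    The model is flat at ``base_mean`` before t0, linear to ``plateau`` at
    t1, flat after; only (t0, t1) are free.  Fitting runs on a neighborhood
    of the threshold anchors wide enough to include true breakpoints that the
    (biased-late) threshold crossings overshot.
    """
    from scipy.optimize import minimize

    width = t_end - t_rise
    margin = max(15.0, width)
    m = (tp >= t_rise - margin) & (tp <= t_end + margin)
    tt, vv = tp[m], vp[m]
    if tt.size < 10:
        return t_rise, t_end

    def sse(params):
        t0, t1 = params
        if not (addition_time <= t0 < t1):
            return 1e300
        model = np.interp(tt, (t0, t1), (base_mean, plateau))
        r = vv - model
        return float(r @ r)

    best = None
    for init in (
        (t_rise, t_end),
        (t_rise - 0.5 * width, t_end),
        (max(t_rise - margin / 2, addition_time), t_end + margin / 4),
    ):
        if not init[0] < init[1]:
            continue
        res = minimize(sse, init, method="Nelder-Mead",
                       options={"xatol": 1e-3, "fatol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        return t_rise, t_end
    t0, t1 = float(best.x[0]), float(best.x[1])
    if t0 >= t1:
        return t_rise, t_end
    return t0, t1


def extension_time_per_monomer(extension_duration: float, ssdna_nt: int) -> float:
    """Per-monomer extension time: duration / (ssDNA nt / 3).

    The RecA site size is 3 nt, so a (dT)60 gap saturates at 20 monomers.
    """
    if ssdna_nt < 3:
        raise ValueError("ssdna_nt must be >= 3")
    if extension_duration < 0:
        raise ValueError("extension_duration must be >= 0")
    return extension_duration / (ssdna_nt / 3.0)
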