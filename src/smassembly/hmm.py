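"""Two-state Gaussian-emission hidden Markov idealization of FRET traces.

A trace's per-frame efficiency is modelled as a two-state Markov chain
(bound/low-E vs unbound/high-E) with Gaussian emissions.  Fitting is plain
Baum-Welch (EM with the scaled forward-backward recursions); the idealized
path is the Viterbi maximum a posteriori joint path.  States are always
relabelled so state 0 has the lower mean (bound) and state 1 the higher
(unbound), making downstream dwell analysis invariant to initialization.

The module also provides the histogram route to the association equilibrium
constant: a two-component Gaussian mixture fit to pooled efficiency values,
whose low-/high-E weight ratio equals K_eq for a stationary cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .traces import BOUND, UNBOUND, FretTrace, StatePath, fret_efficiency  # noqa: F401

_TINY = 1e-300


@njit(cache=False)
def _forward_backward(b, a, pi):
    """Scaled forward-backward for a 2-state HMM.

    Parameters: emission likelihoods ``b`` (T, 2), transition matrix ``a``
    (2, 2), initial distribution ``pi`` (2,).  Returns (loglik, gamma, xi_sum)
    with gamma the per-frame posteriors and xi_sum the expected transition
    counts summed over time.
    """
    T = b.shape[0]
    alpha = np.empty((T, 2))
    c = np.empty(T)
    a0 = pi[0] * b[0, 0]
    a1 = pi[1] * b[0, 1]
    c0 = a0 + a1
    if c0 <= 0.0:
        c0 = _TINY
    alpha[0, 0] = a0 / c0
    alpha[0, 1] = a1 / c0
    c[0] = c0
    for t in range(1, T):
        a0 = (alpha[t - 1, 0] * a[0, 0] + alpha[t - 1, 1] * a[1, 0]) * b[t, 0]
        a1 = (alpha[t - 1, 0] * a[0, 1] + alpha[t - 1, 1] * a[1, 1]) * b[t, 1]
        ct = a0 + a1
        if ct <= 0.0:
            ct = _TINY
        alpha[t, 0] = a0 / ct
        alpha[t, 1] = a1 / ct
        c[t] = ct

    beta = np.empty((T, 2))
    beta[T - 1, 0] = 1.0
    beta[T - 1, 1] = 1.0
    xi = np.zeros((2, 2))
    for t in range(T - 2, -1, -1):
        bb0 = b[t + 1, 0] * beta[t + 1, 0]
        bb1 = b[t + 1, 1] * beta[t + 1, 1]
        beta[t, 0] = (a[0, 0] * bb0 + a[0, 1] * bb1) / c[t + 1]
        beta[t, 1] = (a[1, 0] * bb0 + a[1, 1] * bb1) / c[t + 1]
        denom = c[t + 1]
        xi[0, 0] += alpha[t, 0] * a[0, 0] * bb0 / denom
        xi[0, 1] += alpha[t, 0] * a[0, 1] * bb1 / denom
        xi[1, 0] += alpha[t, 1] * a[1, 0] * bb0 / denom
        xi[1, 1] += alpha[t, 1] * a[1, 1] * bb1 / denom

    gamma = alpha * beta
    for t in range(T):
        s = gamma[t, 0] + gamma[t, 1]
        if s > 0.0:
            gamma[t, 0] /= s
            gamma[t, 1] /= s
    loglik = 0.0
    for t in range(T):
        loglik += np.log(c[t])
    return loglik, gamma, xi


@njit(cache=False)
def _viterbi(logb, loga, logpi):
    """MAP state path for a 2-state HMM; ties prefer staying in-state."""
    T = logb.shape[0]
    delta0 = logpi[0] + logb[0, 0]
    delta1 = logpi[1] + logb[0, 1]
    psi = np.empty((T, 2), dtype=np.int8)
    for t in range(1, T):
        # state 0: stay from 0 vs switch from 1 (tie -> stay)
        s00 = delta0 + loga[0, 0]
        s10 = delta1 + loga[1, 0]
        if s00 >= s10:
            psi[t, 0] = 0
            nd0 = s00 + logb[t, 0]
        else:
            psi[t, 0] = 1
            nd0 = s10 + logb[t, 0]
        s11 = delta1 + loga[1, 1]
        s01 = delta0 + loga[0, 1]
        if s11 >= s01:
            psi[t, 1] = 1
            nd1 = s11 + logb[t, 1]
        else:
            psi[t, 1] = 0
            nd1 = s01 + logb[t, 1]
        delta0, delta1 = nd0, nd1
    path = np.empty(T, dtype=np.int8)
    path[T - 1] = 0 if delta0 >= delta1 else 1
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


@njit(cache=False)
def _baum_welch(x, means, sds, a, pi, tol, max_iter, sigma_floor):
    """Full Baum-Welch EM loop for the 2-state Gaussian HMM (in-place style).

    Returns (means, sds, a, pi, history, n_iter, converged); ``history`` is
    the per-iteration log-likelihood (length n_iter).
    """
    T = x.shape[0]
    b = np.empty((T, 2))
    history = np.empty(max_iter)
    prev_ll = -np.inf
    converged = False
    n_iter = 0
    inv_sqrt2pi = 1.0 / np.sqrt(2.0 * np.pi)
    for it in range(max_iter):
        n_iter = it + 1
        for t in range(T):
            for s in range(2):
                z = (x[t] - means[s]) / sds[s]
                val = np.exp(-0.5 * z * z) * inv_sqrt2pi / sds[s]
                b[t, s] = val if val > _TINY else _TINY
        ll, gamma, xi = _forward_backward(b, a, pi)
        history[it] = ll
        if it > 0 and ll - prev_ll < tol:
            converged = True
            break
        prev_ll = ll
        w0 = 0.0
        w1 = 0.0
        m0 = 0.0
        m1 = 0.0
        for t in range(T):
            w0 += gamma[t, 0]
            w1 += gamma[t, 1]
            m0 += gamma[t, 0] * x[t]
            m1 += gamma[t, 1] * x[t]
        if w0 < 1e-12:
            w0 = 1e-12
        if w1 < 1e-12:
            w1 = 1e-12
        mu0 = m0 / w0
        mu1 = m1 / w1
        v0 = 0.0
        v1 = 0.0
        for t in range(T):
            v0 += gamma[t, 0] * (x[t] - mu0) ** 2
            v1 += gamma[t, 1] * (x[t] - mu1) ** 2
        means[0] = mu0
        means[1] = mu1
        sds[0] = max(np.sqrt(v0 / w0), sigma_floor)
        sds[1] = max(np.sqrt(v1 / w1), sigma_floor)
        for i in range(2):
            row = xi[i, 0] + xi[i, 1]
            if row > 1e-12:
                a[i, 0] = xi[i, 0] / row
                a[i, 1] = xi[i, 1] / row
        p0 = max(gamma[0, 0], 1e-12)
        p1 = max(gamma[0, 1], 1e-12)
        pi[0] = p0 / (p0 + p1)
        pi[1] = p1 / (p0 + p1)
    return means, sds, a, pi, history[:n_iter], n_iter, converged


def _emission_likelihood(x, means, sds):
    z = (x[:, None] - means[None, :]) / sds[None, :]
    b = np.exp(-0.5 * z * z) / (np.sqrt(2 * np.pi) * sds[None, :])
    return np.maximum(b, _TINY)


def forward_loglik(means, sds, transmat, startprob, efficiency):
    """Log-likelihood of an efficiency series under fixed HMM parameters."""
    x = np.asarray(efficiency, dtype=float)
    b = _emission_likelihood(x, np.asarray(means, float), np.asarray(sds, float))
    ll, _, _ = _forward_backward(
        b, np.asarray(transmat, float), np.asarray(startprob, float)
    )
    return float(ll)


@dataclass
class TwoStateHMMResults:
    """Fitted two-state HMM (state 0 = bound/low-E, state 1 = unbound/high-E)."""

    means: np.ndarray
    sds: np.ndarray
    transmat: np.ndarray
    startprob: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    low_evidence: bool
    frame_interval: float
    loglik_history: np.ndarray = field(default=None, repr=False)
    model: object = field(default=None, repr=False)

    @property
    def mu_low(self):
        return float(self.means[0])

    @property
    def mu_high(self):
        return float(self.means[1])

    def viterbi(self, efficiency=None, trace_id="") -> StatePath:
        """Viterbi MAP path; defaults to the series the model was fit on."""
        if efficiency is None:
            efficiency = self.model.efficiency
        x = np.asarray(efficiency, dtype=float)
        logb = np.log(_emission_likelihood(x, self.means, self.sds))
        with np.errstate(divide="ignore"):
            loga = np.log(np.maximum(self.transmat, _TINY))
            logpi = np.log(np.maximum(self.startprob, _TINY))
        states = _viterbi(logb, loga, logpi)
        return StatePath(
            states=states,
            frame_interval=self.frame_interval,
            ideal_e=self.means[states],
            low_evidence=self.low_evidence,
            trace_id=trace_id,
        )

    def predict_proba(self, efficiency=None):
        """Per-frame posterior state probabilities (smoothed, gamma)."""
        if efficiency is None:
            efficiency = self.model.efficiency
        x = np.asarray(efficiency, dtype=float)
        b = _emission_likelihood(x, self.means, self.sds)
        _, gamma, _ = _forward_backward(b, self.transmat, self.startprob)
        return gamma

    def summary(self):
        a = self.transmat
        lines = [
            "Two-state Gaussian HMM (Baum-Welch)",
            "-" * 44,
            f"state 0 (bound/low-E):    mu={self.means[0]:8.4f}  sd={self.sds[0]:7.4f}",
            f"state 1 (unbound/high-E): mu={self.means[1]:8.4f}  sd={self.sds[1]:7.4f}",
            f"transition/frame:  [[{a[0,0]:.5f} {a[0,1]:.5f}]",
            f"                    [{a[1,0]:.5f} {a[1,1]:.5f}]]",
            f"start prob: [{self.startprob[0]:.4f} {self.startprob[1]:.4f}]",
            f"log-likelihood {self.loglik:.4f}  iter {self.n_iter}"
            f"  converged={self.converged}",
        ]
        if self.low_evidence:
            lines.append("NOTE: emission means nearly equal; one-state data likely")
        return "\n".join(lines)

    def plot(self, trace: FretTrace = None, ax=None):
        """Plot the efficiency series with the idealized path overlaid."""
        import matplotlib.pyplot as plt

        eff = trace.efficiency if trace is not None else self.model.efficiency
        dt = trace.frame_interval if trace is not None else self.frame_interval
        t = np.arange(len(eff)) * dt
        path = self.viterbi(eff)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(t, eff, lw=0.5, color="0.6", label="E")
        ax.plot(t, path.ideal_e, lw=1.2, color="tab:orange", label="idealized")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("FRET efficiency")
        ax.legend(loc="best", fontsize="small")
        return ax


class TwoStateHMM:
    """Two-state Gaussian HMM for one efficiency series.

    Parameters
    ----------
    efficiency : array_like
        Per-frame FRET efficiencies (non-finite frames are dropped).
    frame_interval : float, seconds.
    """

    def __init__(self, efficiency, frame_interval=0.05):
        x = np.asarray(efficiency, dtype=float)
        x = x[np.isfinite(x)]
        if x.size < 20:
            raise ValueError("need at least 20 finite frames to fit an HMM")
        self.efficiency = x
        self.frame_interval = float(frame_interval)

    def _default_init(self):
        x = self.efficiency
        lo, hi = np.percentile(x, [10, 90])
        if hi - lo <= 0:
            lo, hi = x.min(), x.max() + 1e-6
        sd = max((hi - lo) / 2.0, 1e-3)
        return (
            np.array([lo, hi]),
            np.array([sd, sd]),
            np.array([[0.95, 0.05], [0.05, 0.95]]),
            np.array([0.5, 0.5]),
        )

    def fit(self, init=None, tol=1e-6, max_iter=500, sigma_floor=1e-3,
            min_separation=0.2) -> TwoStateHMMResults:
        """Baum-Welch fit.

        Iterates until the log-likelihood improves by less than ``tol`` or
        ``max_iter`` is reached; the log-likelihood is non-decreasing along
        the way.  ``sigma_floor`` prevents emission-variance collapse.  A fit
        whose relabelled means differ by less than ``min_separation`` E-units
        is flagged ``low_evidence`` (effectively one-level data).
        """
        x = self.efficiency
        if init is None:
            means, sds, a, pi = self._default_init()
        else:
            means = np.asarray(init["means"], float).copy()
            sds = np.asarray(init["sds"], float).copy()
            a = np.asarray(init["transmat"], float).copy()
            pi = np.asarray(init["startprob"], float).copy()
        means = means.astype(float).copy()
        sds = np.maximum(sds.astype(float), sigma_floor)

        means, sds, a, pi, history, n_iter, converged = _baum_welch(
            x, means, sds, a.astype(float).copy(), pi.astype(float).copy(),
            float(tol), int(max_iter), float(sigma_floor),
        )

        # relabel so state 0 = low mean (bound)
        if means[0] > means[1]:
            order = np.array([1, 0])
            means, sds = means[order], sds[order]
            a = a[np.ix_(order, order)]
            pi = pi[order]
        low_evidence = bool(means[1] - means[0] < min_separation)
        return TwoStateHMMResults(
            means=means,
            sds=sds,
            transmat=a,
            startprob=pi,
            loglik=float(history[-1]),
            n_iter=n_iter,
            converged=converged,
            low_evidence=low_evidence,
            frame_interval=self.frame_interval,
            loglik_history=np.asarray(history),
            model=self,
        )


def fit_two_state_hmm(efficiency, init=None, tol=1e-6, max_iter=500,
                      frame_interval=0.05, **kwargs) -> TwoStateHMMResults:
    """Fit a two-state Gaussian HMM to one efficiency series."""
    return TwoStateHMM(efficiency, frame_interval=frame_interval).fit(
        init=init, tol=tol, max_iter=max_iter, **kwargs
    )


def viterbi_path(results: TwoStateHMMResults, efficiency=None, trace_id="") -> StatePath:
    """Viterbi idealization under a fitted model (ties prefer staying)."""
    return results.viterbi(efficiency, trace_id=trace_id)


def idealize_trace(trace: FretTrace, bound_threshold=0.45, **fit_kwargs):
    """Full idealization of one trace: efficiency -> HMM fit -> Viterbi path.

    Non-finite efficiency frames are dropped before fitting and re-inserted
    into the path by forward fill.  A low-evidence fit (one-level data) yields
    a constant path, classified bound if the mean efficiency lies below
    ``bound_threshold`` (i.e. a molecule stably bound throughout, as for long
    ssDNA where binding precedes observation) and unbound otherwise.

    Returns ``(TwoStateHMMResults, StatePath)``.
    """
    eff = trace.efficiency
    finite = np.isfinite(eff)
    res = TwoStateHMM(eff[finite], frame_interval=trace.frame_interval).fit(**fit_kwargs)
    if res.low_evidence:
        state = BOUND if float(np.nanmean(eff)) < bound_threshold else UNBOUND
        states = np.full(len(eff), state, dtype=np.int8)
        path = StatePath(
            states=states,
            frame_interval=trace.frame_interval,
            ideal_e=np.full(len(eff), float(np.nanmean(eff))),
            low_evidence=True,
            trace_id=trace.trace_id,
        )
        return res, path
    sub = res.viterbi(eff[finite], trace_id=trace.trace_id)
    states = np.empty(len(eff), dtype=np.int8)
    states[finite] = sub.states
    if not finite.all():
        idx = np.where(finite)[0]
        pos = np.searchsorted(idx, np.arange(len(eff)), side="right") - 1
        pos = np.clip(pos, 0, idx.size - 1)
        states = sub.states[pos]
    path = StatePath(
        states=states,
        frame_interval=trace.frame_interval,
        ideal_e=res.means[states],
        low_evidence=False,
        trace_id=trace.trace_id,
    )
    return res, path


def truncate_bleached(trace: FretTrace, background_frac=0.3, min_run=10):
    """Drop frames after photobleaching (both channels at background).

    Bleaching is called at the first run of ``min_run`` frames whose total
    intensity falls below ``background_frac`` times the initial median total;
    the returned trace stops there.  Returns the trace unchanged when no
    bleach is found.
    """
    total = trace.donor + trace.acceptor
    ref = np.median(total[: max(min_run, len(trace) // 10)])
    low = total < background_frac * ref
    run = 0
    for i, flag in enumerate(low):
        run = run + 1 if flag else 0
        if run >= min_run:
            stop = i - min_run + 1
            return FretTrace(
                time=trace.time[:stop],
                donor=trace.donor[:stop],
                acceptor=trace.acceptor[:stop],
                trace_id=trace.trace_id,
            )
    return trace


@dataclass
class FretHistogramFit:
    """Two-component Gaussian-mixture fit to pooled efficiency values."""

    bin_edges: np.ndarray
    counts: np.ndarray
    w_low: float
    w_high: float
    means: np.ndarray
    sds: np.ndarray
    converged: bool = True
    single_component: bool = False


def fit_fret_histogram(efficiencies, n_bins=50, seed=0, bound_threshold=0.45,
                       min_separation=0.2) -> FretHistogramFit:
    """EM fit of a two-Gaussian mixture to pooled per-frame efficiencies.

    The component weights are the low-/high-E population fractions used by
    the histogram route to K_eq.  Requires >= 200 pooled frames.  When the
    fit does not converge, or the fitted component means are closer than
    ``min_separation`` (one-level data, which a two-component EM would
    otherwise split arbitrarily), a single-component result is returned with
    all weight on the side of the pooled mean relative to
    ``bound_threshold``.
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(efficiencies, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 200:
        raise ValueError("need at least 200 pooled frames")
    counts, edges = np.histogram(x, bins=n_bins)
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=3)
    gm.fit(x[:, None])
    means = np.sort(gm.means_.ravel())
    if not gm.converged_ or means[1] - means[0] < min_separation:
        mu = float(x.mean())
        low = mu < bound_threshold
        return FretHistogramFit(
            bin_edges=edges, counts=counts,
            w_low=1.0 if low else 0.0, w_high=0.0 if low else 1.0,
            means=np.array([mu, mu]), sds=np.array([x.std()] * 2),
            converged=bool(gm.converged_), single_component=True,
        )
    order = np.argsort(gm.means_.ravel())
    sds = np.sqrt(gm.covariances_.ravel())[order]
    w = gm.weights_[order]
    return FretHistogramFit(
        bin_edges=edges, counts=counts,
        w_low=float(w[0]), w_high=float(w[1]),
        means=means, sds=sds, converged=True,
    )


def keq_from_histogram(fit: FretHistogramFit) -> float:
    """Association equilibrium constant as low-/high-E population ratio.

    For a stationary two-state cohort the bound (low-E) occupancy is
    k_f/(k_f+k_d), so w_low/w_high = k_f/k_d = K_eq.  Returns ``inf`` when
    the high-E population is empty.
    """
    if fit.w_high == 0.0:
        return np.inf
    return fit.w_low / fit.w_high
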