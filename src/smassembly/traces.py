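"""Core in-memory containers for single-molecule time traces.

Two modalities are supported:

* tethered particle motion (TPM): bead-centroid positions at ~33 ms/frame,
  whose windowed scatter (Brownian-motion amplitude, BM) reports on the
  effective tether length;
* single-molecule FRET: donor/acceptor intensities at ~50 ms/frame, whose
  ratio reports on the dye-pair separation and hence on protein binding.

State convention used throughout the package: ``BOUND = 0`` is the
protein-bound, low-FRET (extended ssDNA) state and ``UNBOUND = 1`` is the
bare-DNA, high-FRET state.  After relabelling, HMM state 0 always has the
lower mean FRET efficiency, so the two orderings coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BOUND = 0
UNBOUND = 1

STATE_NAMES = {BOUND: "bound", UNBOUND: "unbound"}


def fret_efficiency(donor, acceptor):
    """Per-frame apparent FRET efficiency E = I_A / (I_D + I_A).

    No gamma, crosstalk or background correction is applied; background
    subtraction, if wanted, is the caller's concern.  Frames where the total
    intensity is not positive have no defined efficiency and are returned as
    NaN (the idealization drops them).

    Parameters
    ----------
    donor, acceptor : array_like
        Donor and acceptor intensities (camera counts), same shape.

    Returns
    -------
    numpy.ndarray
        Efficiency values; NaN where ``donor + acceptor <= 0``.
    """
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    total = donor + acceptor
    with np.errstate(divide="ignore", invalid="ignore"):
        eff = np.where(total > 0, acceptor / total, np.nan)
    return eff


def _check_time_grid(time, tol=1e-6):
    time = np.asarray(time, dtype=float)
    if time.ndim != 1 or time.size == 0:
        raise ValueError("time must be a non-empty 1-D array")
    if time.size > 1:
        dt = np.diff(time)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0)) + 1
            raise ValueError(f"time must be strictly increasing (index {bad})")
        if np.ptp(dt) > tol:
            raise ValueError("time grid is not uniform within tolerance")
    return time


@dataclass
class BeadTrace:
    """A TPM bead-centroid time series.

    Attributes
    ----------
    time : ndarray, seconds, uniform grid
    x, y : ndarray, bead-centroid position in nm
    valid : ndarray of bool
        False during the flow dead time (and any other frames the
        acquisition flags unusable); analysis skips invalid frames.
    trace_id : str
    """

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray = None
    trace_id: str = ""

    def __post_init__(self):
        self.time = _check_time_grid(self.time)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.time.size, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.time.size
        if not (self.x.size == self.y.size == self.valid.size == n):
            raise ValueError("time, x, y, valid must have equal length")
        if not np.all(np.isfinite(self.x[self.valid])) or not np.all(
            np.isfinite(self.y[self.valid])
        ):
            raise ValueError("x/y must be finite on valid frames")

    @property
    def frame_interval(self):
        return float(self.time[1] - self.time[0]) if self.time.size > 1 else np.nan

    def __len__(self):
        return self.time.size


@dataclass
class FretTrace:
    """A donor/acceptor intensity time series for one molecule."""

    time: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    trace_id: str = ""

    def __post_init__(self):
        self.time = _check_time_grid(self.time)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if not (self.donor.size == self.acceptor.size == self.time.size):
            raise ValueError("time, donor, acceptor must have equal length")

    @property
    def efficiency(self):
        """Per-frame apparent FRET efficiency (NaN where undefined)."""
        return fret_efficiency(self.donor, self.acceptor)

    @property
    def frame_interval(self):
        return float(self.time[1] - self.time[0]) if self.time.size > 1 else np.nan

    def __len__(self):
        return self.time.size


@dataclass
class StatePath:
    """A per-frame two-state idealization of a FRET trace.

    ``states`` holds BOUND (0, low-E) / UNBOUND (1, high-E) labels; ``ideal_e``
    the corresponding state-mean efficiency per frame.  ``low_evidence`` marks
    traces where the fitted emission means were too close to support a
    two-state reading; such paths are constant and are classified bound or
    unbound from the overall mean efficiency.
    """

    states: np.ndarray
    frame_interval: float
    ideal_e: np.ndarray = None
    low_evidence: bool = False
    trace_id: str = ""

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 1 or self.states.size == 0:
            raise ValueError("states must be a non-empty 1-D array")
        if not np.isin(self.states, [BOUND, UNBOUND]).all():
            raise ValueError("states must contain only BOUND/UNBOUND labels")
        if self.ideal_e is not None:
            self.ideal_e = np.asarray(self.ideal_e, dtype=float)
            if self.ideal_e.size != self.states.size:
                raise ValueError("ideal_e must match states length")

    @property
    def duration(self):
        return self.states.size * self.frame_interval

    def __len__(self):
        return self.states.size
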