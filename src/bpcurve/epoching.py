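"""Epoching of a continuous recording into a labeled trial matrix.

A single-pulse stimulation experiment yields one continuous voltage trace
``V(t0)`` from the measurement electrode plus a table of stimulation events.
Each event ``k`` occurred at time ``tau_k`` and carries the label ``n`` of the
stimulated electrode pair (its *subgroup*).  Epoching cuts a fixed window
``[tau_k + t1, tau_k + t2]`` around every pulse and stacks the cut-outs into
the T x K matrix ``V_k(t)``.  Averaging within a subgroup yields the familiar
cortico-cortical evoked potential (CCEP) ``G_n(t)``.

Window convention: event times are snapped to the nearest sample, the first
window sample is the first sample at or after ``tau_k + t1``, and all trials
share the same integer sample count (no interpolation).  With the default
window of 0.050-2.000 s at 2048 Hz this gives T = 3994 samples per trial.
No filtering, re-referencing or detrending is applied here; preprocessing is
the caller's responsibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "EventTable",
    "TrialMatrix",
    "CCEPMatrix",
    "epoch_trials",
    "subgroup_average",
    "window_sample_bounds",
]

#: default analysis window (seconds after the pulse), chosen to start after
#: the stimulation artifact has passed and to end once responses return to
#: baseline
DEFAULT_T1 = 0.050
DEFAULT_T2 = 2.000


def _unique_in_order(labels: np.ndarray) -> np.ndarray:
    """Unique labels in order of first appearance (stimulation order)."""
    _, idx = np.unique(labels, return_index=True)
    return labels[np.sort(idx)]


@dataclass
class EventTable:
    """Stimulation events: onset times (s) and stimulation-pair labels."""

    onset: np.ndarray  # seconds, strictly increasing
    label: np.ndarray  # subgroup label per event (str or int)

    def __post_init__(self) -> None:
        self.onset = np.asarray(self.onset, dtype=float)
        self.label = np.asarray(self.label)
        if self.onset.ndim != 1 or self.onset.shape != self.label.shape:
            raise ValueError("onset and label must be 1-D arrays of equal length")
        if self.onset.size == 0:
            raise ValueError("event table is empty")
        if np.any(np.diff(self.onset) <= 0):
            raise ValueError("event onsets must be strictly increasing")

    @property
    def n_events(self) -> int:
        return self.onset.size

    @property
    def subgroups(self) -> np.ndarray:
        return _unique_in_order(self.label)


@dataclass
class TrialMatrix:
    """Epoched voltage responses: T timepoints x K trials with labels.

    ``values`` is in microvolts; ``time`` is seconds relative to the pulse
    (uniform at 1/fs); ``labels[k]`` names the stimulation-pair subgroup of
    trial k.
    """

    values: np.ndarray  # (T, K) float
    time: np.ndarray  # (T,) seconds relative to pulse
    fs: float  # Hz
    labels: np.ndarray = field(default=None)  # (K,)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (timepoints x trials)")
        if self.time.shape != (self.values.shape[0],):
            raise ValueError("time axis length must match number of timepoints")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trial values must be finite")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        dt = np.diff(self.time)
        if dt.size and not np.allclose(dt, 1.0 / self.fs, rtol=0, atol=1e-9):
            raise ValueError("time axis must be uniform at 1/fs")
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (self.values.shape[1],):
            raise ValueError("labels must cover all trials")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    @property
    def subgroups(self) -> np.ndarray:
        """Subgroup labels in order of first appearance."""
        return _unique_in_order(self.labels)

    def trial_indices(self, label) -> np.ndarray:
        """Column indices of the trials belonging to one subgroup."""
        return np.flatnonzero(self.labels == label)


@dataclass
class CCEPMatrix:
    """Subgroup-averaged evoked potentials G_n(t): T timepoints x N subgroups."""

    values: np.ndarray  # (T, N)
    time: np.ndarray  # (T,)
    labels: np.ndarray  # (N,) subgroup order


def window_sample_bounds(fs: float, t1: float, t2: float) -> tuple[int, int]:
    """Integer sample offsets (relative to the pulse sample) of the window.

    Returns ``(start, stop)`` such that the window covers samples
    ``start .. stop`` inclusive, where ``start`` is the first sample index at
    or after ``t1`` and ``stop`` the last at or before ``t2``.
    """
    if not t1 < t2:
        raise ValueError("t1 must be smaller than t2")
    start = int(np.ceil(t1 * fs - 1e-9))
    stop = int(np.floor(t2 * fs + 1e-9))
    if stop < start:
        raise ValueError("window [t1, t2] contains no sample")
    return start, stop


def epoch_trials(
    raw_trace: np.ndarray,
    fs: float,
    events: EventTable,
    t1: float = DEFAULT_T1,
    t2: float = DEFAULT_T2,
) -> TrialMatrix:
    """Cut the continuous trace into the trial matrix V_k(t).

    Events whose window would run outside the recording are dropped with a
    logged warning; an error is raised if no trial survives.
    """
    raw_trace = np.asarray(raw_trace, dtype=float)
    if raw_trace.ndim != 1:
        raise ValueError("raw_trace must be a 1-D voltage series")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    start, stop = window_sample_bounds(fs, t1, t2)
    n_samp = stop - start + 1

    onset_idx = np.rint(events.onset * fs).astype(int)
    cols, labels = [], []
    for k, (i_on, lab) in enumerate(zip(onset_idx, events.label)):
        i0 = i_on + start
        i1 = i0 + n_samp
        if i0 < 0 or i1 > raw_trace.size:
            logger.warning(
                "dropping trial %d (label %r): window [%d, %d) outside recording "
                "of %d samples",
                k, lab, i0, i1, raw_trace.size,
            )
            continue
        cols.append(raw_trace[i0:i1])
        labels.append(lab)
    if not cols:
        raise ValueError("all trials fell outside the recording")

    values = np.column_stack(cols)
    time = (start + np.arange(n_samp)) / fs
    return TrialMatrix(values=values, time=time, fs=fs, labels=np.asarray(labels))


def subgroup_average(V: TrialMatrix) -> CCEPMatrix:
    """Average trials within each subgroup: G_n(t) = <V_k(t)>_{k in n}."""
    subgroups = V.subgroups
    cols = np.empty((V.n_samples, subgroups.size))
    for j, lab in enumerate(subgroups):
        idx = V.trial_indices(lab)
        if idx.size == 0:  # pragma: no cover - subgroups derives from labels
            raise ValueError(f"subgroup {lab!r} has no trials")
        cols[:, j] = V.values[:, idx].mean(axis=1)
    return CCEPMatrix(values=cols, time=V.time.copy(), labels=subgroups)
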