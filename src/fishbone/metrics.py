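"""Population response statistics: binned counts, Shannon entropy, firing
rate, and the temporal incoherence of the mechanical stimulus itself.

Synchrony is quantified by the Shannon entropy of the distribution of firing
events over time bins: with ``F_i`` events in bin ``i`` and
``p_i = F_i / sum(F)``,

    H = -sum_i p_i ln p_i        (nats)

Low entropy means events crowd into few bins, i.e. the population fires in
synchrony.  The same metric applied to the times of maximum pin displacement
(or maximum displacement change) measures the temporal incoherence of the
stimulus delivered through a pin matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .neuron import SpikeTrainSet
from .stimulus import DisplacementTrace

__all__ = [
    "BinnedCounts",
    "bin_events",
    "shannon_entropy",
    "mean_firing_rate",
    "stimulus_event_times",
    "stimulus_incoherence",
]


@dataclass(frozen=True)
class BinnedCounts:
    """Per-bin event totals over the analysis window ``[0, T]``."""

    counts: np.ndarray
    dt: float
    T: float

    def __post_init__(self) -> None:
        n = round(self.T / self.dt)
        if abs(n * self.dt - self.T) > 1e-9 * max(1.0, self.T):
            raise ValueError("T must be an integer multiple of the bin width")
        if self.counts.shape != (n,):
            raise ValueError(f"expected {n} bins, got {self.counts.shape}")

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def bin_events(events, dt: float = 4.0, T: float = 800.0) -> BinnedCounts:
    """Count events in half-open bins ``[(i-1) dt, i dt)``; the right window
    edge ``T`` folds into the last bin.

    ``events`` is a :class:`SpikeTrainSet` (all afferents pooled) or an
    array-like of event times.  Times outside ``[0, T]`` raise.
    """
    if isinstance(events, SpikeTrainSet):
        times = events.pooled()
    else:
        times = np.sort(np.asarray(events, dtype=float).ravel())
    n = round(T / dt)
    if times.size and (times[0] < 0 or times[-1] > T):
        raise ValueError("event times must lie within [0, T]")
    idx = np.minimum(np.floor(times / dt).astype(int), n - 1)
    counts = np.bincount(idx, minlength=n) if times.size else np.zeros(n, dtype=int)
    return BinnedCounts(counts=counts, dt=dt, T=T)


def shannon_entropy(counts) -> float:
    """Shannon entropy (nats) of the bin-occupancy distribution.

    By convention an empty event set has entropy 0, which keeps the metric
    total (a silent population is maximally synchronised in a trivial sense).
    """
    c = counts.counts if isinstance(counts, BinnedCounts) else np.asarray(counts)
    c = np.asarray(c, dtype=float)
    total = c.sum()
    if total <= 0:
        return 0.0
    p = c[c > 0] / total
    return float(-np.sum(p * np.log(p)))


def mean_firing_rate(counts: BinnedCounts, n_neurons: int) -> float:
    """Mean firing rate per afferent (events/ms): ``sum(F_i) / (T * Nn)``.

    Multiply by 1000 for Hz.
    """
    if n_neurons <= 0:
        raise ValueError("n_neurons must be positive")
    return counts.total / (counts.T * n_neurons)


def _run_compress(x: np.ndarray, tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Values and start indices of maximal runs of near-equal consecutive
    values (difference within ``tol``, guarding against float noise)."""
    change = np.nonzero(np.abs(np.diff(x)) > tol)[0] + 1
    starts = np.concatenate([[0], change])
    return x[starts], starts


def _local_max_times(t: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Times of strict local maxima of a sampled signal.

    A plateau counts once, timed at its first sample; the window endpoints
    are never maxima.  Constant signals yield no events.
    """
    x = np.asarray(x, dtype=float)
    tol = 1e-12 * max(1.0, float(np.max(np.abs(x), initial=0.0)))
    vals, starts = _run_compress(x, tol)
    if vals.size < 3:
        return np.empty(0)
    is_max = (vals[1:-1] > vals[:-2]) & (vals[1:-1] > vals[2:])
    return t[starts[1:-1][is_max]]


def stimulus_event_times(trace: DisplacementTrace, mode: str = "height") -> np.ndarray:
    """Event times of a pin displacement trace.

    ``mode="height"``: strict local maxima of ``h(t)``.
    ``mode="height_change"``: strict local maxima of ``|dh/dt|`` (central
    difference), capturing the steepest rises and falls.
    Constant traces (e.g. pins resting on the spine) yield no events.
    """
    t = trace.t
    h = trace.h
    if mode == "height":
        return _local_max_times(t, h)
    if mode == "height_change":
        rate = np.abs((h[2:] - h[:-2]) / (t[2:] - t[:-2]))
        return _local_max_times(t[1:-1], rate)
    raise ValueError(f"unknown mode {mode!r}")


def stimulus_incoherence(
    traces,
    dt_bin: float = 4.0,
    mode: str = "height_change",
    T: float | None = None,
) -> float:
    """Shannon entropy of pooled stimulus event times across pins.

    Pools the per-pin events of :func:`stimulus_event_times`, bins them with
    the same bin width used for the spike analysis, and applies
    :func:`shannon_entropy`.  Pins whose displacement never varies contribute
    no events.
    """
    traces = list(traces)
    if T is None:
        if not traces:
            raise ValueError("need at least one trace or an explicit T")
        T = float(traces[0].t[-1])
    pooled = [stimulus_event_times(tr, mode=mode) for tr in traces]
    events = np.concatenate(pooled) if pooled else np.empty(0)
    return shannon_entropy(bin_events(events, dt=dt_bin, T=T))
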