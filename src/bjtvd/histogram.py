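"""1-D conductance histograms and 2-D conductance-stretch-length histograms.

The standard BJ summary plots: pooled log-conductance histograms over many
traces, and 2-D histograms of conductance versus stretch length with every
trace re-zeroed at the rupture of the metal contact (the first point whose
conductance drops below a threshold just under the metal plateaus).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .simulate import LabeledTrace

__all__ = [
    "Histogram1D",
    "Histogram2D",
    "align_trace_origin",
    "conductance_histogram",
    "conductance_length_histogram",
    "peak_count",
    "DEFAULT_Y_EDGES",
    "DEFAULT_X_EDGES",
    "DEFAULT_ALIGN_THRESHOLD",
]

# conductance bins span the baseline (-6) through the metal plateaus (~0.3)
DEFAULT_Y_EDGES = np.round(np.arange(-6.0, 1.0 + 1e-9, 0.05), 10)
# stretch-length bins relative to the metal-rupture origin
DEFAULT_X_EDGES = np.round(np.arange(-0.3, 1.5 + 1e-9, 0.01), 10)
DEFAULT_ALIGN_THRESHOLD = -0.3


@dataclass(frozen=True)
class Histogram1D:
    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class Histogram2D:
    x_edges: np.ndarray  # stretch length, nm, from the rupture origin
    y_edges: np.ndarray  # log10(G/G0)
    counts: np.ndarray   # shape (len(x_edges)-1, len(y_edges)-1)


class AlignmentError(ValueError):
    """Raised when a trace never crosses the alignment threshold."""


def _series_for_alignment(trace: LabeledTrace) -> np.ndarray:
    if trace.reconstructed is not None:
        return trace.reconstructed
    if trace.truth_log_g is not None:
        return trace.truth_log_g
    return trace.log_g


def align_trace_origin(trace: LabeledTrace,
                       threshold: float = DEFAULT_ALIGN_THRESHOLD) -> LabeledTrace:
    """Re-zero distance at the rupture of the metal contact.

    The origin is the first point whose reconstructed (or, failing that,
    ground-truth or raw) log conductance drops below ``threshold``; points
    before rupture get negative distances.
    """
    ref = _series_for_alignment(trace)
    below = np.flatnonzero(ref < threshold)
    if below.size == 0:
        raise AlignmentError("trace never drops below the alignment threshold")
    origin = trace.distance[below[0]]
    return replace(trace, distance=trace.distance - origin)


def _check_edges(edges) -> np.ndarray:
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing with >= 2 values")
    return edges


def conductance_histogram(traces: Sequence[LabeledTrace] | Sequence[np.ndarray],
                          edges=DEFAULT_Y_EDGES,
                          use_reconstructed: bool = False) -> Histogram1D:
    """Pool all points of all traces into one log-conductance histogram.

    Accepts LabeledTrace objects or bare arrays.  With ``use_reconstructed``
    the TVD output stored on each trace is binned instead of the raw series.
    """
    edges = _check_edges(edges)
    counts = np.zeros(edges.size - 1, dtype=np.int64)
    for t in traces:
        if isinstance(t, LabeledTrace):
            vals = t.reconstructed if use_reconstructed else t.log_g
            if use_reconstructed and vals is None:
                raise ValueError("trace has no reconstructed series")
        else:
            vals = np.asarray(t, dtype=float)
        counts += np.histogram(vals, bins=edges)[0]
    return Histogram1D(edges, counts)


def conductance_length_histogram(traces: Sequence[LabeledTrace],
                                 x_edges=DEFAULT_X_EDGES,
                                 y_edges=DEFAULT_Y_EDGES,
                                 threshold: float = DEFAULT_ALIGN_THRESHOLD,
                                 use_reconstructed: bool = False,
                                 ) -> Histogram2D:
    """Align every trace at metal rupture, then bin (distance, log_g) pairs.

    Traces that never cross the threshold are skipped (they cannot be
    aligned to a common origin).
    """
    x_edges = _check_edges(x_edges)
    y_edges = _check_edges(y_edges)
    counts = np.zeros((x_edges.size - 1, y_edges.size - 1), dtype=np.int64)
    for t in traces:
        try:
            aligned = align_trace_origin(t, threshold)
        except AlignmentError:
            continue
        vals = aligned.reconstructed if use_reconstructed else aligned.log_g
        if vals is None:
            raise ValueError("trace has no reconstructed series")
        counts += np.histogram2d(aligned.distance, vals,
                                 bins=(x_edges, y_edges))[0].astype(np.int64)
    return Histogram2D(x_edges, y_edges, counts)


def peak_count(hist: Histogram1D, min_prominence: float = 0.1) -> int:
    """Number of histogram peaks with prominence >= min_prominence * max count.

    Standard local-maximum semantics: the first and last bin cannot be
    peaks, so a distribution ramping into the window edge does not count
    as a resolved state.
    """
    counts = np.asarray(hist.counts, dtype=float)
    if counts.size == 0:
        raise ValueError("histogram is empty")
    if counts.max() == 0:
        return 0
    peaks, _ = find_peaks(counts, prominence=min_prominence * counts.max())
    return int(peaks.size)
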