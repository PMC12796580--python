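"""Spike detection, peristimulus time histograms and window firing rates.

The normalization convention is per-sweep: spikes are counted across all
included sweeps and divided by the number of sweeps and the bin (or window)
duration, so 100 spikes over 30 sweeps in a 1-s window give 100/30 = 3.33
spikes/s.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .session import SpikeTrain


class EmptySelectionError(ValueError):
    """No sweeps passed the state filter — a rate would be undefined."""


@dataclass
class Psth:
    """Event-aligned, per-sweep-normalized firing-rate histogram.

    Bins are half-open ``[edge, next_edge)`` in ms relative to the alignment
    event; ``rate`` is spikes/s per bin.
    """

    bin_edges: np.ndarray
    rate: np.ndarray
    n_sweeps: int
    alignment: str = "deflection"
    state_label: str = "all"

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.rate.size != self.bin_edges.size - 1:
            raise ValueError("rate must have one entry per bin")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        if np.any(self.rate < -1e-12):
            raise ValueError("negative rate")

    @property
    def bin_width_ms(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def counts(self) -> np.ndarray:
        """Recover integer spike counts per bin from the normalized rate."""
        return np.rint(self.rate * self.n_sweeps * self.bin_width_ms / 1000.0).astype(int)

    def mean_rate(self, window_ms: tuple[float, float]) -> float:
        """Mean rate over bins whose centers fall inside [lo, hi]."""
        lo, hi = window_ms
        sel = (self.bin_centers >= lo) & (self.bin_centers <= hi)
        if not sel.any():
            raise ValueError("window contains no bins")
        return float(self.rate[sel].mean())

    def save(self, path: str | Path) -> None:
        path = Path(path)
        pd.DataFrame(
            {
                "bin_start_ms": self.bin_edges[:-1],
                "bin_end_ms": self.bin_edges[1:],
                "rate_spikes_per_s": self.rate,
            }
        ).to_csv(path, index=False)
        meta = {
            "n_sweeps": self.n_sweeps,
            "alignment": self.alignment,
            "state_label": self.state_label,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def detect_spikes(
    raw: np.ndarray,
    sample_rate_hz: float,
    band_hz: tuple[float, float] = (300.0, 3000.0),
    threshold_sd: float = 4.0,
    refractory_ms: float = 1.0,
) -> np.ndarray:
    """Threshold spike detection on a raw voltage trace.

    The trace is band-pass filtered (4th-order Butterworth, zero-phase) and
    negative-going excursions beyond ``threshold_sd`` standard deviations of
    the filtered trace are reported; crossings closer than ``refractory_ms``
    merge into one event.  Returns event times in ms.
    """
    raw = np.asarray(raw, dtype=float)
    lo, hi = band_hz
    if sample_rate_hz < 2 * hi:
        raise ValueError("sample rate must be at least twice the band upper edge")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=sample_rate_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, raw)
    sd = float(np.std(filtered))
    if sd == 0.0:
        warnings.warn("flat trace: no spikes detectable", stacklevel=2)
        return np.empty(0)
    below = filtered < -threshold_sd * sd
    onsets = np.flatnonzero(below & ~np.roll(below, 1))
    if below.size and below[0]:
        onsets = np.concatenate([[0], onsets[onsets != 0]])
    times_ms = onsets / sample_rate_hz * 1000.0
    if times_ms.size == 0:
        return times_ms
    keep = [0]
    for i in range(1, times_ms.size):
        if times_ms[i] - times_ms[keep[-1]] >= refractory_ms:
            keep.append(i)
    return times_ms[keep]


def _relative_times(train: SpikeTrain, events: np.ndarray) -> np.ndarray:
    """Spike times relative to each event, concatenated (events × spikes)."""
    return (train.times_ms[None, :] - np.asarray(events, dtype=float)[:, None]).ravel()


def build_psth(
    train: SpikeTrain,
    events: np.ndarray,
    window_ms: tuple[float, float],
    bin_width_ms: float = 2.0,
    alignment: str = "deflection",
    state_label: str = "all",
) -> Psth:
    """Event-aligned PSTH with per-sweep normalization.

    ``events`` are the alignment times (one per sweep); the number of events
    is the normalization denominator.  Bins are half-open, so a spike exactly
    on an edge belongs to the bin to its right.
    """
    events = np.asarray(events, dtype=float)
    if events.size == 0:
        raise ValueError("at least one event is required")
    lo, hi = window_ms
    n_bins = (hi - lo) / bin_width_ms
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_width must divide the window length")
    edges = lo + bin_width_ms * np.arange(int(round(n_bins)) + 1)

    rel = _relative_times(train, events)
    # np.histogram closes the last bin on the right; drop edge-exact spikes there
    counts, _ = np.histogram(rel[rel < hi], bins=edges)
    rate = counts / events.size / (bin_width_ms / 1000.0)
    return Psth(
        bin_edges=edges,
        rate=rate,
        n_sweeps=int(events.size),
        alignment=alignment,
        state_label=state_label,
    )


def window_rate(
    train: SpikeTrain,
    events: np.ndarray,
    window_ms: tuple[float, float],
    state_filter: pd.Series | np.ndarray | None = None,
    include_labels: tuple[str, ...] = ("quiet", "whisking"),
) -> float:
    """Mean firing rate over a window around each included event.

    ``state_filter`` gives one label per event; only events whose label is in
    ``include_labels`` contribute. The denominator is (number of included
    sweeps) × (window duration).
    """
    events = np.asarray(events, dtype=float)
    if state_filter is not None:
        labels = np.asarray(state_filter)
        if labels.size != events.size:
            raise ValueError("state_filter must have one label per event")
        events = events[np.isin(labels, include_labels)]
    if events.size == 0:
        raise EmptySelectionError("no sweeps pass the state filter")
    lo, hi = window_ms
    if hi <= lo:
        raise ValueError("window must be a proper interval")
    rel = _relative_times(train, events)
    count = int(np.count_nonzero((rel >= lo) & (rel < hi)))
    return count / events.size / ((hi - lo) / 1000.0)
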