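"""Evoked-response quantification on averaged PSTHs.

Onset latency follows a consecutive-bins rule: the response begins at the
first 2-ms bin opening a run of at least five bins whose rate exceeds the
baseline mean plus twice the baseline SD.  Further metrics: the early/late
split of biphasic responses (first-order thalamus shows a second component
from ~41 ms), the rising slope from onset to the maximum peak, and
control-minus-photoinactivation rate differences over a stated window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .psth import Psth

EARLY_WINDOW_MS = (5.0, 40.0)
LATE_WINDOW_MS = (41.0, 100.0)


@dataclass
class ResponseMetrics:
    onset_latency_ms: float | None
    peak_rate: float
    peak_time_ms: float
    slope: float | None  # spikes/s per ms
    wer1_rate: float
    wer2_rate: float
    delta_rate: float | None = None


def detect_response_onset(
    p: Psth,
    baseline_window_ms: float = 200.0,
    k_sd: float = 2.0,
    min_consecutive: int = 5,
) -> float | None:
    """First post-stimulus bin opening a run of supra-threshold bins.

    Threshold = baseline mean + k_sd × baseline SD, with baseline statistics
    taken from the bins in the ``baseline_window_ms`` before time zero.  A bin
    qualifies only if its rate is strictly greater than the threshold; the
    onset is the left edge of the first bin starting a run of at least
    ``min_consecutive`` qualifying bins, or None when no such run exists.
    """
    centers = p.bin_centers
    base_sel = (centers >= -baseline_window_ms) & (centers < 0)
    if base_sel.sum() < 2:
        raise ValueError("baseline needs at least two bins")
    base = p.rate[base_sel]
    threshold = float(base.mean() + k_sd * base.std(ddof=0))

    starts = p.bin_edges[:-1]
    post = np.flatnonzero(starts >= 0)
    above = p.rate[post] > threshold
    i = 0
    while i < above.size:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < above.size and above[j]:
            j += 1
        if j - i >= min_consecutive:
            return float(starts[post[i]])
        i = j
    return None


def find_peak(
    p: Psth, onset_ms: float, window_end_ms: float = 100.0
) -> tuple[float, float]:
    """(peak_rate, peak_time) over [onset, window_end]; ties take the earliest bin."""
    centers = p.bin_centers
    sel = (centers >= onset_ms) & (centers <= window_end_ms)
    if not sel.any():
        raise ValueError("no bins between onset and window end")
    rates = p.rate[sel]
    i = int(np.argmax(rates))  # argmax returns the first maximum
    return float(rates[i]), float(centers[sel][i])


def split_biphasic(
    p: Psth,
    early_ms: tuple[float, float] = EARLY_WINDOW_MS,
    late_ms: tuple[float, float] = LATE_WINDOW_MS,
    baseline_subtract: bool = False,
    baseline_window_ms: float = 200.0,
) -> tuple[float, float]:
    """Mean rate in the early and late response windows.

    Windows must be disjoint and post-stimulus; bins are attributed by their
    centers.  With ``baseline_subtract`` the pre-stimulus mean is removed from
    both (clipped at zero).
    """
    if early_ms[1] > late_ms[0] and late_ms[1] > early_ms[0]:
        if not (early_ms[1] <= late_ms[0] or late_ms[1] <= early_ms[0]):
            raise ValueError("early and late windows overlap")
    if early_ms[0] < 0 or late_ms[0] < 0:
        raise ValueError("windows must be post-stimulus")
    wer1 = p.mean_rate(early_ms)
    wer2 = p.mean_rate(late_ms)
    if baseline_subtract:
        base = p.mean_rate((-baseline_window_ms, -1e-9))
        wer1 = max(wer1 - base, 0.0)
        wer2 = max(wer2 - base, 0.0)
    return wer1, wer2


def response_slope(p: Psth, onset_ms: float, peak_time_ms: float) -> float:
    """OLS slope of bin rate against bin-center time over [onset, peak], in
    spikes/s per ms."""
    if onset_ms >= peak_time_ms:
        raise ValueError("onset must precede the peak")
    centers = p.bin_centers
    sel = (centers >= onset_ms) & (centers <= peak_time_ms)
    if sel.sum() < 2:
        raise ValueError("degenerate interval: onset and peak share a bin")
    x = centers[sel]
    y = p.rate[sel]
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def condition_delta(
    p_ctrl: Psth, p_opto: Psth, window_ms: tuple[float, float]
) -> float:
    """Control minus photoinactivation mean rate over a shared window."""
    if p_ctrl.alignment != p_opto.alignment:
        raise ValueError("PSTHs must share the alignment event")
    if not np.allclose(p_ctrl.bin_edges, p_opto.bin_edges):
        raise ValueError("PSTHs must share binning")
    if p_ctrl.state_label != p_opto.state_label:
        raise ValueError("PSTHs must share the state label")
    return p_ctrl.mean_rate(window_ms) - p_opto.mean_rate(window_ms)


def response_metrics(
    p: Psth,
    baseline_window_ms: float = 200.0,
    analysis_end_ms: float = 100.0,
) -> ResponseMetrics:
    """Full metric set for one averaged PSTH."""
    onset = detect_response_onset(p, baseline_window_ms=baseline_window_ms)
    wer1, wer2 = split_biphasic(p)
    if onset is None:
        centers = p.bin_centers
        sel = (centers >= 0) & (centers <= analysis_end_ms)
        rates = p.rate[sel]
        i = int(np.argmax(rates))
        return ResponseMetrics(None, float(rates[i]), float(centers[sel][i]), None, wer1, wer2)
    peak_rate, peak_time = find_peak(p, onset, analysis_end_ms)
    slope = None
    if peak_time > onset:
        try:
            slope = response_slope(p, onset, peak_time)
        except ValueError:
            slope = None
    return ResponseMetrics(onset, peak_rate, peak_time, slope, wer1, wer2)
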