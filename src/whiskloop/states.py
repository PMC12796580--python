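"""Brain-state segmentation from the LFP spectrogram.

Quiet non-whisking epochs carry their dominant LFP power at 4–12 Hz while
whisking epochs shift power into higher bands (13–30 and 25–60 Hz).  The
classifier slides a Welch window along the trace, integrates linear power over
the quiet band and over the union of the active bands, and labels each window
by the active/quiet power ratio; ambiguous windows — the stand-in for "active
non-whisking" epochs, which cannot be told apart without video — are excluded
from all downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .session import LfpTrace, Session, StateIntervals

QUIET_BAND = (4.0, 12.0)
ACTIVE_BANDS = ((13.0, 30.0), (25.0, 60.0))

#: Spectrogram defaults: 500 ms windows stepped by 125 ms resolve both the
#: 4 Hz band edge (2 Hz frequency resolution) and sub-second bout boundaries.
DEFAULT_WINDOW_MS = 500.0
DEFAULT_OVERLAP = 0.75
DEFAULT_RATIO_THRESHOLD = 1.5
DEFAULT_MIN_EPISODE_MS = 500.0


@dataclass
class Spectrogram:
    """Sliding-window Welch PSD on a log-power (dB) scale."""

    window_times: np.ndarray  # window start, ms
    frequencies: np.ndarray  # Hz, increasing
    psd_db: np.ndarray  # (n_windows, n_freqs), 10*log10 power
    window_length_ms: float
    overlap_fraction: float

    @property
    def step_ms(self) -> float:
        return self.window_length_ms * (1.0 - self.overlap_fraction)

    def linear_psd(self) -> np.ndarray:
        return 10.0 ** (self.psd_db / 10.0)


def compute_spectrogram(
    lfp: LfpTrace,
    window_length_ms: float = DEFAULT_WINDOW_MS,
    overlap_fraction: float = DEFAULT_OVERLAP,
) -> Spectrogram:
    """Welch PSD in sliding windows over the whole trace.

    Each window is analysed as a single Hann-tapered segment, giving a
    frequency resolution of 1000/window_length_ms Hz.  Power is stored in dB;
    a tiny floor keeps the log finite for silent traces.
    """
    fs = lfp.sample_rate_hz
    nper = int(round(window_length_ms / 1000.0 * fs))
    if nper < 2 or nper > lfp.samples.size:
        raise ValueError("window length must fit inside the trace")
    if not (0.0 <= overlap_fraction < 1.0):
        raise ValueError("overlap_fraction must lie in [0, 1)")
    step = max(int(round(nper * (1.0 - overlap_fraction))), 1)

    starts = np.arange(0, lfp.samples.size - nper + 1, step)
    rows = []
    for i0 in starts:
        freqs, pxx = signal.welch(
            lfp.samples[i0 : i0 + nper], fs=fs, nperseg=nper, window="hann"
        )
        rows.append(pxx)
    psd = np.asarray(rows)
    psd_db = 10.0 * np.log10(np.maximum(psd, 1e-300))
    return Spectrogram(
        window_times=lfp.start_ms + starts / fs * 1000.0,
        frequencies=freqs,
        psd_db=psd_db,
        window_length_ms=nper / fs * 1000.0,
        overlap_fraction=1.0 - step / nper,
    )


def band_power(
    frequencies: np.ndarray, linear_psd: np.ndarray, bands: tuple | list
) -> np.ndarray:
    """Integrate linear PSD over a band or a union of (possibly overlapping)
    bands; overlap regions are counted once."""
    if np.isscalar(bands[0]):
        bands = (bands,)
    mask = np.zeros(frequencies.shape, dtype=bool)
    for lo, hi in bands:
        mask |= (frequencies >= lo) & (frequencies <= hi)
    if not mask.any():
        raise ValueError("no frequency bins fall inside the requested band(s)")
    return np.trapezoid(linear_psd[:, mask], frequencies[mask], axis=1)


def classify_states(
    spec: Spectrogram,
    quiet_band: tuple[float, float] = QUIET_BAND,
    active_bands: tuple = ACTIVE_BANDS,
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    min_episode_ms: float = DEFAULT_MIN_EPISODE_MS,
) -> StateIntervals:
    """Label the session quiet / whisking / excluded from band-power ratios.

    Per window the ratio R = P_active / P_quiet decides the label:
    whisking if R > ratio_threshold, quiet if R < 1/ratio_threshold, excluded
    otherwise (ties go to exclusion).  Window labels are assigned to
    contiguous step-long segments, merged, and episodes shorter than
    ``min_episode_ms`` are relabelled excluded.
    """
    if spec.psd_db.size == 0:
        raise ValueError("empty spectrogram")
    lin = spec.linear_psd()
    p_quiet = band_power(spec.frequencies, lin, quiet_band)
    p_active = band_power(spec.frequencies, lin, active_bands)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = p_active / p_quiet

    labels = np.full(ratio.shape, "excluded", dtype=object)
    labels[ratio > ratio_threshold] = "whisking"
    labels[ratio < 1.0 / ratio_threshold] = "quiet"

    # each window's label covers [center - step/2, center + step/2)
    centers = spec.window_times + spec.window_length_ms / 2.0
    step = spec.step_ms
    t0 = float(spec.window_times[0])
    t_end = float(spec.window_times[-1] + spec.window_length_ms)
    seg_starts = np.maximum(centers - step / 2.0, t0)
    seg_ends = np.minimum(centers + step / 2.0, t_end)
    seg_starts[0] = t0
    seg_ends[-1] = t_end

    rows = []
    for s, e, lab in zip(seg_starts, seg_ends, labels):
        if rows and rows[-1]["label"] == lab and abs(rows[-1]["end_ms"] - s) < 1e-9:
            rows[-1]["end_ms"] = e
        else:
            rows.append({"start_ms": float(s), "end_ms": float(e), "label": str(lab)})

    # short-episode removal, then re-merge adjacent excluded stretches
    for r in rows:
        if r["end_ms"] - r["start_ms"] < min_episode_ms:
            r["label"] = "excluded"
    merged: list[dict] = []
    for r in rows:
        if merged and merged[-1]["label"] == r["label"]:
            merged[-1]["end_ms"] = r["end_ms"]
        else:
            merged.append(r)
    return StateIntervals(pd.DataFrame(merged), provenance="classified")


def assign_sweep_states(
    states: StateIntervals,
    session: Session,
    analysis_window_ms: tuple[float, float] = (-200.0, 100.0),
    align: str = "deflection",
) -> pd.Series:
    """Per-sweep state label relative to the alignment event.

    A sweep is labelled quiet or whisking only when a single interval of that
    label covers its entire analysis window (a purity rule); any sweep that
    straddles a state transition or touches excluded time is excluded.
    """
    lo, hi = analysis_window_ms
    if hi <= lo:
        raise ValueError("analysis window must be a proper interval")
    col = {"deflection": "deflection_ms", "trigger": "trigger_ms", "light_on": "light_on_ms"}[
        align
    ]
    anchors = session.events[col].to_numpy(dtype=float)
    if np.any(anchors + lo < 0) or np.any(anchors + hi > session.duration_ms):
        raise ValueError("analysis window extends outside the session")
    out = []
    for a in anchors:
        label = states.covering_interval(a + lo, a + hi)
        out.append(label if label in ("quiet", "whisking") else "excluded")
    return pd.Series(out, index=session.events["sweep_id"].to_numpy(), name="state")


def interval_overlap_fraction(truth: StateIntervals, classified: StateIntervals) -> float:
    """Fraction of the session over which classified labels match the truth.

    Excluded classified time counts as non-matching; the denominator is the
    full truth duration.
    """
    edges = np.unique(
        np.concatenate(
            [
                truth.intervals[["start_ms", "end_ms"]].to_numpy().ravel(),
                classified.intervals[["start_ms", "end_ms"]].to_numpy().ravel(),
            ]
        )
    )
    total = float(truth.intervals["end_ms"].max() - truth.intervals["start_ms"].min())
    mids = (edges[:-1] + edges[1:]) / 2.0
    widths = np.diff(edges)
    t_lab = truth.label_at(mids)
    c_lab = classified.label_at(mids)
    inside = (mids >= truth.intervals["start_ms"].min()) & (
        mids < truth.intervals["end_ms"].max()
    )
    match = (t_lab == c_lab) & (t_lab != "excluded") & inside
    return float(widths[match].sum() / total)
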