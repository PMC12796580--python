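"""In-memory containers for one recording/simulation session and their CSV layout.

A session bundles everything the downstream analysis consumes: an event log of
sweeps (one row per stimulation repetition), per-unit spike trains with
metadata, a local-field-potential trace, and — for simulated sessions —
ground-truth behavioural-state intervals.

All times are in milliseconds from session start unless a name says otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Stimulation conditions: light pulse only, air puff only, or both combined.
CONDITIONS = ("opto_only", "puff_only", "combined")

#: Behavioural-state vocabulary used throughout.
STATE_LABELS = ("quiet", "whisking", "excluded")

EVENT_COLUMNS = [
    "sweep_id",
    "condition",
    "trigger_ms",
    "light_on_ms",
    "light_off_ms",
    "deflection_ms",
]


@dataclass(frozen=True)
class WaveformFeatures:
    """Scalar extracellular-waveform features used for interneuron screening.

    peak_amplitude_asymmetry is dimensionless; trough_to_peak and half_width
    are in milliseconds and must be positive.
    """

    peak_amplitude_asymmetry: float
    trough_to_peak: float
    half_width: float

    def __post_init__(self) -> None:
        if self.trough_to_peak <= 0 or self.half_width <= 0:
            raise ValueError("trough_to_peak and half_width must be > 0")


@dataclass
class SpikeTrain:
    """Sorted spike times (ms) of one unit plus its metadata.

    Ground-truth fields (``is_tagged``, ``is_interneuron``, ``structure``) are
    carried along for simulated units so classifier recovery can be scored.
    """

    unit_id: str
    times_ms: np.ndarray
    structure: str = "S1"  # S1 | POm | VPM
    depth_um: float = float("nan")
    waveform: WaveformFeatures | None = None
    is_tagged: bool | None = None
    is_interneuron: bool | None = None

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.times_ms.ndim != 1:
            raise ValueError("spike times must be a 1-D array")
        if np.any(np.diff(self.times_ms) < 0):
            raise ValueError(f"spike times of {self.unit_id} not sorted")

    def __len__(self) -> int:
        return self.times_ms.size


@dataclass
class LfpTrace:
    """Uniformly sampled LFP, arbitrary units."""

    samples: np.ndarray
    sample_rate_hz: float
    start_ms: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")

    @property
    def duration_ms(self) -> float:
        return self.samples.size / self.sample_rate_hz * 1000.0

    def times_ms(self) -> np.ndarray:
        return self.start_ms + np.arange(self.samples.size) / self.sample_rate_hz * 1000.0


@dataclass
class StateIntervals:
    """Labelled, non-overlapping, sorted behavioural-state intervals.

    ``provenance`` records whether the labels are simulation ground truth
    (``"truth"``) or the output of the LFP classifier (``"classified"``).
    """

    intervals: pd.DataFrame  # columns start_ms, end_ms, label
    provenance: str = "truth"

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.intervals, columns=["start_ms", "end_ms", "label"])
        if len(df):
            if not df["label"].isin(STATE_LABELS).all():
                bad = sorted(set(df["label"]) - set(STATE_LABELS))
                raise ValueError(f"unknown state labels: {bad}")
            df = df.sort_values("start_ms", ignore_index=True)
            if np.any(df["end_ms"].to_numpy() <= df["start_ms"].to_numpy()):
                raise ValueError("empty or inverted interval")
            if np.any(df["start_ms"].to_numpy()[1:] < df["end_ms"].to_numpy()[:-1] - 1e-9):
                raise ValueError("intervals overlap")
        self.intervals = df

    def label_at(self, t_ms: np.ndarray) -> np.ndarray:
        """Label for each query time; times outside any interval get 'excluded'."""
        t = np.atleast_1d(np.asarray(t_ms, dtype=float))
        out = np.full(t.shape, "excluded", dtype=object)
        starts = self.intervals["start_ms"].to_numpy()
        ends = self.intervals["end_ms"].to_numpy()
        labels = self.intervals["label"].to_numpy()
        idx = np.searchsorted(starts, t, side="right") - 1
        ok = (idx >= 0) & (t < ends[np.clip(idx, 0, max(len(ends) - 1, 0))])
        out[ok] = labels[idx[ok]]
        return out

    def covering_interval(self, start_ms: float, end_ms: float) -> str | None:
        """Return the label of a single interval covering [start, end), else None."""
        df = self.intervals
        hit = df[(df["start_ms"] <= start_ms) & (df["end_ms"] >= end_ms)]
        if len(hit) == 0:
            return None
        return str(hit.iloc[0]["label"])

    def total_duration(self, label: str) -> float:
        df = self.intervals
        sel = df[df["label"] == label]
        return float((sel["end_ms"] - sel["start_ms"]).sum())


@dataclass
class Session:
    """One experiment: event log, spike trains, LFP and state intervals."""

    events: pd.DataFrame
    units: list[SpikeTrain]
    lfp: LfpTrace | None
    state_truth: StateIntervals | None
    duration_ms: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise ValueError(f"event log missing columns: {missing}")

    def unit(self, unit_id: str) -> SpikeTrain:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def sweeps(self, condition: str | None = None) -> pd.DataFrame:
        if condition is None:
            return self.events
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        return self.events[self.events["condition"] == condition]

    # ------------------------------------------------------------------ I/O

    def save(self, out_dir: str | Path) -> None:
        """Write the documented CSV directory layout."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.events.to_csv(out / "events.csv", index=False)

        rows = []
        for u in self.units:
            wf = u.waveform
            rows.append(
                {
                    "unit_id": u.unit_id,
                    "structure": u.structure,
                    "depth_um": u.depth_um,
                    "peak_amplitude_asymmetry": wf.peak_amplitude_asymmetry if wf else np.nan,
                    "trough_to_peak_ms": wf.trough_to_peak if wf else np.nan,
                    "half_width_ms": wf.half_width if wf else np.nan,
                    "is_tagged": u.is_tagged,
                    "is_interneuron": u.is_interneuron,
                }
            )
        pd.DataFrame(rows).to_csv(out / "units.csv", index=False)

        spikes = pd.DataFrame(
            {
                "unit_id": np.concatenate(
                    [np.repeat(u.unit_id, len(u)) for u in self.units]
                )
                if self.units
                else [],
                "time_ms": np.concatenate([u.times_ms for u in self.units])
                if self.units
                else [],
            }
        )
        spikes.to_csv(out / "spikes.csv", index=False)

        if self.lfp is not None:
            pd.DataFrame({"lfp": self.lfp.samples}).to_csv(out / "lfp.csv", index=False)
        if self.state_truth is not None:
            self.state_truth.intervals.to_csv(out / "states_truth.csv", index=False)

        meta = dict(self.meta)
        meta["duration_ms"] = self.duration_ms
        if self.lfp is not None:
            meta["lfp_sample_rate_hz"] = self.lfp.sample_rate_hz
        (out / "session.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def load(cls, in_dir: str | Path) -> "Session":
        src = Path(in_dir)
        meta = json.loads((src / "session.json").read_text())
        events = pd.read_csv(src / "events.csv")
        units_df = pd.read_csv(src / "units.csv")
        spikes = pd.read_csv(src / "spikes.csv")
        units = []
        for _, row in units_df.iterrows():
            wf = None
            if np.isfinite(row["trough_to_peak_ms"]):
                wf = WaveformFeatures(
                    row["peak_amplitude_asymmetry"],
                    row["trough_to_peak_ms"],
                    row["half_width_ms"],
                )
            t = spikes.loc[spikes["unit_id"] == row["unit_id"], "time_ms"].to_numpy()
            units.append(
                SpikeTrain(
                    unit_id=str(row["unit_id"]),
                    times_ms=np.sort(t),
                    structure=str(row["structure"]),
                    depth_um=float(row["depth_um"]),
                    waveform=wf,
                    is_tagged=None if pd.isna(row["is_tagged"]) else bool(row["is_tagged"]),
                    is_interneuron=None
                    if pd.isna(row["is_interneuron"])
                    else bool(row["is_interneuron"]),
                )
            )
        lfp = None
        if (src / "lfp.csv").exists():
            lfp = LfpTrace(
                pd.read_csv(src / "lfp.csv")["lfp"].to_numpy(),
                meta["lfp_sample_rate_hz"],
            )
        truth = None
        if (src / "states_truth.csv").exists():
            truth = StateIntervals(pd.read_csv(src / "states_truth.csv"), provenance="truth")
        duration = meta.pop("duration_ms")
        meta.pop("lfp_sample_rate_hz", None)
        return cls(
            events=events,
            units=units,
            lfp=lfp,
            state_truth=truth,
            duration_ms=duration,
            meta=meta,
        )
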