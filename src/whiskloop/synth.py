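"""Synthetic recording sessions with known ground truth.

The generator emulates an awake head-restrained whisker-stimulation experiment:
blocks of sweeps for three stimulation conditions (light pulse only, air puff
only, combined) are delivered in randomized order, the animal alternates
between quiet and whisking bouts, and each unit fires as an inhomogeneous
Poisson process whose rate reflects its baseline, the behavioural state, a
photo-suppression factor during light pulses, and an additive whisker-evoked
transient after each air puff (optionally biphasic, as in first-order
thalamus).

Every stochastic element is driven by named sub-streams of one session seed,
so a session is bit-reproducible and adding a unit does not perturb the
others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session import (
    CONDITIONS,
    EVENT_COLUMNS,
    LfpTrace,
    Session,
    SpikeTrain,
    StateIntervals,
    WaveformFeatures,
)


class ConfigurationError(ValueError):
    """Raised when a protocol / unit / state configuration is inconsistent."""


# --------------------------------------------------------------------------- configs


@dataclass(frozen=True)
class ProtocolConfig:
    """Timing of the stimulation protocol.

    Defaults reproduce the standard protocol: thirty sweeps per condition,
    air puffs of 20 ms delivered at 0.5 Hz with ~10 ms air travel delay, and a
    70 ms light pulse starting 50 ms before the deflection reaches the
    whiskers (so the pulse ends together with the puff). The whole cycle of
    three condition blocks is repeated twice.
    """

    n_sweeps_per_condition: int = 30
    conditions: tuple[str, ...] = CONDITIONS
    n_cycles: int = 2
    puff_count: int = 25
    puff_duration_ms: float = 20.0
    puff_rate_hz: float = 0.5
    air_delay_ms: float = 10.0
    light_duration_ms: float = 70.0
    light_lead_ms: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sweeps_per_condition < 1:
            raise ConfigurationError("n_sweeps_per_condition must be >= 1")
        if self.n_cycles < 1:
            raise ConfigurationError("n_cycles must be >= 1")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ConfigurationError(f"unknown conditions: {sorted(unknown)}")
        if self.light_lead_ms < 0:
            raise ConfigurationError("light_lead_ms must be >= 0")
        for name in ("puff_duration_ms", "puff_rate_hz", "light_duration_ms"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.air_delay_ms < 0:
            raise ConfigurationError("air_delay_ms must be >= 0")

    @property
    def inter_sweep_ms(self) -> float:
        return 1000.0 / self.puff_rate_hz


@dataclass(frozen=True)
class WerKernel:
    """Whisker-evoked rate transient: linear rise then exponential decay.

    The kernel is 0 before ``onset_ms``, rises linearly to 1 at ``peak_ms``
    and decays as exp(-(t - peak)/decay_ms) afterwards.  Its time integral is
    (peak - onset)/2 + decay_ms (in ms), which makes expected evoked spike
    counts available in closed form.
    """

    onset_ms: float = 5.0
    peak_ms: float = 12.0
    decay_ms: float = 15.0

    def __post_init__(self) -> None:
        if not (0 <= self.onset_ms < self.peak_ms):
            raise ConfigurationError("require 0 <= onset < peak")
        if self.decay_ms <= 0:
            raise ConfigurationError("decay_ms must be > 0")

    def __call__(self, tau_ms: np.ndarray) -> np.ndarray:
        tau = np.asarray(tau_ms, dtype=float)
        out = np.zeros_like(tau)
        rising = (tau >= self.onset_ms) & (tau < self.peak_ms)
        out[rising] = (tau[rising] - self.onset_ms) / (self.peak_ms - self.onset_ms)
        decaying = tau >= self.peak_ms
        out[decaying] = np.exp(-(tau[decaying] - self.peak_ms) / self.decay_ms)
        return out

    @property
    def integral_ms(self) -> float:
        """Integral of the unit-peak kernel over all time, in ms."""
        return (self.peak_ms - self.onset_ms) / 2.0 + self.decay_ms


@dataclass(frozen=True)
class SecondComponent:
    """Optional late evoked component (e.g. the second peak of VPM responses)."""

    onset_ms: float = 41.0
    amplitude: float = 10.0
    decay_ms: float = 15.0
    rise_ms: float = 5.0

    def kernel(self) -> WerKernel:
        return WerKernel(self.onset_ms, self.onset_ms + self.rise_ms, self.decay_ms)


@dataclass(frozen=True)
class UnitSpec:
    """Ground-truth firing model of one simulated unit.

    The instantaneous rate is

        r(t) = base_rate * m_state(t) * m_opto(t) + wer(t)

    where ``m_state`` is ``whisking_multiplier`` during whisking bouts and 1
    otherwise, ``m_opto`` is ``opto_suppression`` inside
    [light_on + opto_latency, light_off] of light sweeps and 1 otherwise, and
    ``wer`` sums ``wer_amplitude * kernel(t - deflection)`` over puff sweeps
    (plus the optional late component).
    """

    unit_id: str
    structure: str = "S1"
    depth_um: float = 800.0
    base_rate: float = 5.0
    whisking_multiplier: float = 2.0
    opto_suppression: float = 1.0
    opto_latency_ms: float = 2.0
    wer_amplitude: float = 0.0
    wer_kernel: WerKernel = field(default_factory=WerKernel)
    wer_second_component: SecondComponent | None = None
    is_tagged: bool = False
    is_interneuron: bool = False
    waveform: WaveformFeatures = field(
        default_factory=lambda: WaveformFeatures(0.4, 0.6, 0.35)
    )

    def __post_init__(self) -> None:
        if self.base_rate < 0:
            raise ConfigurationError("base_rate must be >= 0")
        if self.whisking_multiplier < 1:
            raise ConfigurationError("whisking_multiplier must be >= 1")
        if not (0.0 <= self.opto_suppression <= 1.0):
            raise ConfigurationError("opto_suppression must lie in [0, 1]")
        if self.opto_latency_ms < 0:
            raise ConfigurationError("opto_latency_ms must be >= 0")
        if self.wer_amplitude < 0:
            raise ConfigurationError("wer_amplitude must be >= 0")
        sc = self.wer_second_component
        if sc is not None and sc.onset_ms <= self.wer_kernel.peak_ms:
            raise ConfigurationError("second component must start after the first peak")

    @property
    def max_rate(self) -> float:
        """Upper bound on r(t), used by the thinning sampler."""
        second = self.wer_second_component.amplitude if self.wer_second_component else 0.0
        return self.base_rate * self.whisking_multiplier + self.wer_amplitude + second


@dataclass(frozen=True)
class StateConfig:
    """Behavioural-state and LFP model.

    Quiet and whisking bouts alternate with exponentially distributed
    durations (clipped from below) and the LFP is a sum of band-limited
    oscillations — drawn from ``quiet_band`` during quiet bouts and from the
    union of ``active_bands`` during whisking — plus white noise.
    """

    quiet_mean_ms: float = 3000.0
    whisking_mean_ms: float = 2000.0
    min_episode_ms: float = 500.0
    quiet_band: tuple[float, float] = (4.0, 12.0)
    active_bands: tuple[tuple[float, float], ...] = ((13.0, 30.0), (25.0, 60.0))
    lfp_sample_rate_hz: float = 1000.0
    lfp_noise_sd: float = 0.5
    osc_amplitude: float = 1.0
    n_components: int = 3

    def __post_init__(self) -> None:
        if not self.active_bands or self.quiet_band[1] < self.quiet_band[0]:
            raise ConfigurationError("bands must be non-empty")
        top = max(hi for _, hi in self.active_bands)
        if self.lfp_sample_rate_hz <= 2 * max(top, self.quiet_band[1]):
            raise ConfigurationError("sample rate must exceed twice the highest band edge")
        if self.n_components < 1:
            raise ConfigurationError("n_components must be >= 1")


# --------------------------------------------------------------------------- helpers


def _unit_rng(seed: int, unit_id: str) -> np.random.Generator:
    # deterministic per-unit sub-stream; adding units never perturbs others
    return np.random.default_rng([seed, 3, zlib.crc32(unit_id.encode())])


def generate_state_truth(
    duration_ms: float, cfg: StateConfig, seed: int
) -> StateIntervals:
    """Alternating quiet/whisking bouts tiling [0, duration_ms)."""
    rng = np.random.default_rng([seed, 1])
    rows = []
    t = 0.0
    label = "quiet"
    while t < duration_ms:
        mean = cfg.quiet_mean_ms if label == "quiet" else cfg.whisking_mean_ms
        dur = max(rng.exponential(mean), cfg.min_episode_ms)
        end = min(t + dur, duration_ms)
        rows.append({"start_ms": t, "end_ms": end, "label": label})
        t = end
        label = "whisking" if label == "quiet" else "quiet"
    return StateIntervals(pd.DataFrame(rows), provenance="truth")


def _build_events(protocol: ProtocolConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Randomized condition blocks; nominal light/deflection times recorded for
    every sweep so any sweep can serve as an alignment reference — whether the
    puff or pulse is actually delivered is given by ``condition``."""
    isi = protocol.inter_sweep_ms
    t = max(isi / 2.0, protocol.light_lead_ms + 100.0)  # lead-in before first trigger
    rows = []
    sweep_id = 0
    for _cycle in range(protocol.n_cycles):
        order = rng.permutation(len(protocol.conditions))
        for ci in order:
            cond = protocol.conditions[ci]
            for _ in range(protocol.n_sweeps_per_condition):
                deflection = t + protocol.air_delay_ms
                light_on = deflection - protocol.light_lead_ms
                rows.append(
                    {
                        "sweep_id": sweep_id,
                        "condition": cond,
                        "trigger_ms": t,
                        "light_on_ms": light_on,
                        "light_off_ms": light_on + protocol.light_duration_ms,
                        "deflection_ms": deflection,
                    }
                )
                sweep_id += 1
                t += isi
            t += isi  # gap between condition blocks
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def _in_any_interval(t: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Membership of each t in a set of disjoint sorted intervals."""
    if starts.size == 0:
        return np.zeros(t.shape, dtype=bool)
    idx = np.searchsorted(starts, t, side="right") - 1
    idx_c = np.clip(idx, 0, starts.size - 1)
    return (idx >= 0) & (t < ends[idx_c])


def unit_rate(
    spec: UnitSpec, session: Session, t_ms: np.ndarray
) -> np.ndarray:
    """Ground-truth instantaneous rate r(t) in spikes/s at the given times."""
    t = np.asarray(t_ms, dtype=float)
    rate = np.full(t.shape, spec.base_rate)

    truth = session.state_truth
    if truth is not None and spec.whisking_multiplier != 1.0:
        whisk = truth.intervals[truth.intervals["label"] == "whisking"]
        inw = _in_any_interval(
            t, whisk["start_ms"].to_numpy(), whisk["end_ms"].to_numpy()
        )
        rate[inw] *= spec.whisking_multiplier

    ev = session.events
    light = ev[ev["condition"].isin(["opto_only", "combined"])]
    if len(light) and spec.opto_suppression != 1.0:
        on = np.sort(light["light_on_ms"].to_numpy()) + spec.opto_latency_ms
        off = np.sort(light["light_off_ms"].to_numpy())
        rate[_in_any_interval(t, on, off)] *= spec.opto_suppression

    puff = ev[ev["condition"].isin(["puff_only", "combined"])]
    if len(puff) and (spec.wer_amplitude > 0 or spec.wer_second_component):
        defl = np.sort(puff["deflection_ms"].to_numpy())
        idx = np.searchsorted(defl, t, side="right") - 1
        tau = np.where(idx >= 0, t - defl[np.clip(idx, 0, defl.size - 1)], -1.0)
        if spec.wer_amplitude > 0:
            rate += spec.wer_amplitude * spec.wer_kernel(tau)
        if spec.wer_second_component is not None:
            sc = spec.wer_second_component
            rate += sc.amplitude * sc.kernel()(tau)
    return rate


def generate_unit_spiketrain(
    spec: UnitSpec, session: Session, seed: int
) -> SpikeTrain:
    """Sample one unit's spikes by thinning a homogeneous Poisson process.

    Candidates are drawn at the unit's rate upper bound over the whole session
    and kept with probability r(t)/r_max, which is exact for any kernel shape.
    """
    rng = _unit_rng(seed, spec.unit_id)
    rmax = spec.max_rate
    duration_s = session.duration_ms / 1000.0
    n_cand = rng.poisson(rmax * duration_s)
    cand = np.sort(rng.uniform(0.0, session.duration_ms, size=n_cand))
    if n_cand == 0 or rmax == 0:
        times = np.empty(0)
    else:
        r = unit_rate(spec, session, cand)
        if np.any(r < 0):  # impossible by construction; guard against regressions
            raise RuntimeError("negative instantaneous rate")
        keep = rng.uniform(0.0, rmax, size=n_cand) < r
        times = cand[keep]
    return SpikeTrain(
        unit_id=spec.unit_id,
        times_ms=times,
        structure=spec.structure,
        depth_um=spec.depth_um,
        waveform=spec.waveform,
        is_tagged=spec.is_tagged,
        is_interneuron=spec.is_interneuron,
    )


def generate_lfp(
    state_truth: StateIntervals, cfg: StateConfig, seed: int
) -> LfpTrace:
    """Band-limited LFP whose dominant power tracks the behavioural state.

    Each bout gets ``n_components`` sinusoids with frequencies drawn uniformly
    from the quiet band (quiet bouts) or the union of the active bands
    (whisking bouts), random phases, and additive white noise.
    """
    if len(state_truth.intervals) == 0:
        raise ConfigurationError("state intervals must tile the session")
    rng = np.random.default_rng([seed, 2])
    fs = cfg.lfp_sample_rate_hz
    duration_ms = float(state_truth.intervals["end_ms"].max())
    n = int(round(duration_ms / 1000.0 * fs))
    t_s = np.arange(n) / fs
    samples = rng.normal(0.0, cfg.lfp_noise_sd, size=n)

    active_lo = min(lo for lo, _ in cfg.active_bands)
    active_hi = max(hi for _, hi in cfg.active_bands)
    amp = cfg.osc_amplitude / np.sqrt(cfg.n_components)
    for _, row in state_truth.intervals.iterrows():
        if row["label"] == "quiet":
            lo, hi = cfg.quiet_band
        elif row["label"] == "whisking":
            lo, hi = active_lo, active_hi
        else:
            continue
        i0 = int(round(row["start_ms"] / 1000.0 * fs))
        i1 = int(round(row["end_ms"] / 1000.0 * fs))
        seg_t = t_s[i0:i1]
        freqs = rng.uniform(lo, hi, size=cfg.n_components)
        phases = rng.uniform(0.0, 2 * np.pi, size=cfg.n_components)
        for f, ph in zip(freqs, phases):
            samples[i0:i1] += amp * np.sin(2 * np.pi * f * seg_t + ph)
    return LfpTrace(samples=samples, sample_rate_hz=fs)


# --------------------------------------------------------------------------- session


def generate_session(
    protocol: ProtocolConfig,
    units: list[UnitSpec],
    states: StateConfig | None = None,
    include_lfp: bool = True,
) -> Session:
    """Simulate a full session: event log, state truth, LFP and spike trains.

    Identical (configs, seed) yield a bit-identical session. ``include_lfp``
    can be switched off for spike-only simulations (e.g. large statistical
    replications) where synthesizing the LFP would dominate the runtime.
    """
    if not units:
        raise ConfigurationError("at least one unit is required")
    ids = [u.unit_id for u in units]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("unit_ids must be unique")
    states = states or StateConfig()

    seed = protocol.seed
    events = _build_events(protocol, np.random.default_rng([seed, 0]))
    duration_ms = float(events["trigger_ms"].max() + protocol.inter_sweep_ms)
    truth = generate_state_truth(duration_ms, states, seed)

    session = Session(
        events=events,
        units=[],
        lfp=None,
        state_truth=truth,
        duration_ms=duration_ms,
        meta={"seed": seed, "n_sweeps": int(len(events))},
    )
    session.units = [generate_unit_spiketrain(u, session, seed) for u in units]
    if include_lfp:
        session.lfp = generate_lfp(truth, states, seed)
    return session
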