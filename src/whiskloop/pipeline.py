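"""End-to-end orchestration: simulate → segment → classify → quantify → test.

`run_pipeline` generates (or loads) a session, segments behavioural states
from the LFP, classifies units (opto-tag, interneuron, layer), builds
per-sweep-normalized PSTHs for every unit × state × condition cell, applies
the exclusion rules (interneurons, unclassifiable units, ROUT outliers on
per-unit difference scores), and runs the repeated-measures statistics,
mirroring the summary-table layout of the source experiments.

"Control" is the puff-only condition and "opto" the combined
light-plus-puff condition; spontaneous rates are measured from light onset to
deflection (a 50 ms window present in both conditions) and evoked rates over
the 100 ms after the deflection reaches the whiskers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from . import metrics as met
from . import states as st
from . import stats as wstats
from . import synth
from .psth import Psth, build_psth, window_rate
from .session import Session


@dataclass(frozen=True)
class PopulationConfig:
    """Composition of the simulated unit population.

    Default rates and multipliers emulate the recorded regimes: low cortical
    baselines that roughly double during whisking, full fast photo-suppression
    of tagged layer-6 cells, partial suppression of their POm targets, and a
    biphasic evoked response in VPM.
    """

    n_tagged: int = 10
    n_l6_other: int = 10
    n_pom: int = 10
    n_vpm: int = 10
    n_interneurons: int = 2
    base_rate_range: tuple[float, float] = (2.0, 10.0)
    whisking_multiplier: float = 2.0
    tagged_suppression: float = 0.0
    tagged_latency_ms: float = 2.0
    pom_suppression: float = 0.5
    pom_latency_ms: float = 6.0
    vpm_suppression: float = 1.0
    wer_amplitude: float = 30.0
    vpm_second_amplitude: float = 12.0


@dataclass(frozen=True)
class AnalysisConfig:
    bin_width_ms: float = 2.0
    sweep_state_window_ms: tuple[float, float] = (-200.0, 100.0)
    spont_window_ms: tuple[float, float] = (-50.0, 0.0)
    wer_window_ms: tuple[float, float] = (0.0, 100.0)
    psth_window_ms: tuple[float, float] = (-200.0, 100.0)
    anova_design: str = "both_within"
    rout_q_percent: float = 1.0
    min_sweeps_per_cell: int = 3


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    seed: int = 0
    protocol: synth.ProtocolConfig = field(default_factory=synth.ProtocolConfig)
    states: synth.StateConfig = field(default_factory=synth.StateConfig)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self) -> None:
        if self.protocol.seed != self.seed:
            self.protocol = dataclasses.replace(self.protocol, seed=self.seed)

    def to_yaml(self, path: str | Path) -> None:
        def plain(obj):
            if dataclasses.is_dataclass(obj):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [plain(v) for v in obj]
            return obj

        Path(path).write_text(yaml.safe_dump(plain(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())

        def tup(x):
            if isinstance(x, list):
                return tuple(tup(v) for v in x)
            return x

        def build(dc, d):
            fields = {f.name: f for f in dataclasses.fields(dc)}
            kwargs = {k: tup(v) for k, v in d.items() if k in fields}
            return dc(**kwargs)

        return cls(
            seed=raw.get("seed", 0),
            protocol=build(synth.ProtocolConfig, raw.get("protocol", {})),
            states=build(synth.StateConfig, raw.get("states", {})),
            population=build(PopulationConfig, raw.get("population", {})),
            analysis=build(AnalysisConfig, raw.get("analysis", {})),
        )


@dataclass
class PipelineResult:
    summary: pd.DataFrame
    metrics: pd.DataFrame
    anova: pd.DataFrame
    posthoc: pd.DataFrame
    exclusions: dict
    log: dict
    session: Session
    psths: dict  # (class, state, condition) -> list of (unit_id, Psth)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(out / "summary.csv", index=False)
        self.metrics.to_csv(out / "metrics.csv", index=False)
        self.anova.to_csv(out / "anova.csv", index=False)
        self.posthoc.to_csv(out / "posthoc.csv", index=False)
        (out / "run_log.json").write_text(
            json.dumps({"exclusions": self.exclusions, **self.log}, indent=2, sort_keys=True)
        )


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def build_population(cfg: PopulationConfig, seed: int) -> list[synth.UnitSpec]:
    """Deterministic unit specs for the default simulated population."""
    rng = np.random.default_rng([seed, 10])
    lo, hi = cfg.base_rate_range
    units: list[synth.UnitSpec] = []

    def rate() -> float:
        return float(rng.uniform(lo, hi))

    excitatory_wf = lambda: synth.WaveformFeatures(  # noqa: E731 - terse local factory
        float(rng.uniform(0.2, 0.6)), float(rng.uniform(0.4, 0.8)), float(rng.uniform(0.25, 0.5))
    )
    fs_wf = lambda: synth.WaveformFeatures(  # noqa: E731
        float(rng.uniform(0.2, 0.5)), float(rng.uniform(0.1, 0.25)), float(rng.uniform(0.08, 0.18))
    )

    for i in range(cfg.n_tagged):
        units.append(
            synth.UnitSpec(
                unit_id=f"tag{i:03d}",
                structure="S1",
                depth_um=float(rng.uniform(780, 1000)),
                base_rate=rate(),
                whisking_multiplier=cfg.whisking_multiplier,
                opto_suppression=cfg.tagged_suppression,
                opto_latency_ms=cfg.tagged_latency_ms,
                wer_amplitude=cfg.wer_amplitude,
                wer_kernel=synth.WerKernel(8.0, 14.0, 12.0),
                is_tagged=True,
                waveform=excitatory_wf(),
            )
        )
    for i in range(cfg.n_l6_other):
        units.append(
            synth.UnitSpec(
                unit_id=f"l6o{i:03d}",
                structure="S1",
                depth_um=float(rng.uniform(780, 1000)),
                base_rate=rate(),
                whisking_multiplier=cfg.whisking_multiplier,
                opto_suppression=1.0,
                wer_amplitude=cfg.wer_amplitude,
                wer_kernel=synth.WerKernel(8.0, 14.0, 12.0),
                is_tagged=False,
                waveform=excitatory_wf(),
            )
        )
    for i in range(cfg.n_pom):
        units.append(
            synth.UnitSpec(
                unit_id=f"pom{i:03d}",
                structure="POm",
                depth_um=float("nan"),
                base_rate=rate(),
                whisking_multiplier=cfg.whisking_multiplier,
                opto_suppression=cfg.pom_suppression,
                opto_latency_ms=cfg.pom_latency_ms,
                wer_amplitude=cfg.wer_amplitude,
                wer_kernel=synth.WerKernel(6.0, 12.0, 12.0),
                is_tagged=False,
                waveform=excitatory_wf(),
            )
        )
    for i in range(cfg.n_vpm):
        units.append(
            synth.UnitSpec(
                unit_id=f"vpm{i:03d}",
                structure="VPM",
                depth_um=float("nan"),
                base_rate=rate(),
                whisking_multiplier=cfg.whisking_multiplier,
                opto_suppression=cfg.vpm_suppression,
                wer_amplitude=cfg.wer_amplitude,
                wer_kernel=synth.WerKernel(5.0, 10.0, 10.0),
                wer_second_component=synth.SecondComponent(
                    onset_ms=41.0, amplitude=cfg.vpm_second_amplitude, decay_ms=15.0
                ),
                is_tagged=False,
                waveform=excitatory_wf(),
            )
        )
    for i in range(cfg.n_interneurons):
        units.append(
            synth.UnitSpec(
                unit_id=f"int{i:03d}",
                structure="S1",
                depth_um=float(rng.uniform(780, 1000)),
                base_rate=float(rng.uniform(8, 20)),
                whisking_multiplier=cfg.whisking_multiplier,
                opto_suppression=1.0,
                wer_amplitude=cfg.wer_amplitude,
                is_tagged=False,
                is_interneuron=True,
                waveform=fs_wf(),
            )
        )
    return units


def _unit_class(train, tag_result: str) -> str:
    if train.structure in ("POm", "VPM"):
        return train.structure
    return "L6-tagged" if tag_result == "tagged" else "L6-other"


def run_pipeline(cfg: RunConfig, session: Session | None = None) -> PipelineResult:
    """Execute every stage on a simulated (or provided) session."""
    ana = cfg.analysis

    # ---------------------------------------------------------------- simulate
    if session is None:
        try:
            units = build_population(cfg.population, cfg.seed)
            if not units:
                raise synth.ConfigurationError("empty unit population")
            session = synth.generate_session(cfg.protocol, units, cfg.states)
        except synth.ConfigurationError as e:
            raise PipelineError("simulate", str(e)) from e

    # ----------------------------------------------------------------- states
    try:
        spec = st.compute_spectrogram(session.lfp)
        classified = st.classify_states(spec)
        sweep_state = st.assign_sweep_states(
            classified, session, analysis_window_ms=ana.sweep_state_window_ms
        )
    except (ValueError, KeyError) as e:
        raise PipelineError("states", str(e)) from e

    ev = session.events
    census = (
        pd.DataFrame({"condition": ev["condition"].to_numpy(), "state": sweep_state.to_numpy()})
        .value_counts()
        .rename("n_sweeps")
        .reset_index()
        .sort_values(["condition", "state"], ignore_index=True)
    )

    # --------------------------------------------------------------- classify
    opto_ev = ev[ev["condition"] == "opto_only"]
    if len(opto_ev) == 0:
        raise PipelineError("classify", "no light-only sweeps for opto-tagging")
    classifications = {}
    for u in session.units:
        if u.structure == "S1":
            p_light = build_psth(
                u,
                opto_ev["light_on_ms"].to_numpy(),
                window_ms=(-200.0, 70.0),
                bin_width_ms=ana.bin_width_ms,
                alignment="light_on",
            )
            tag = clf.classify_optotag(p_light)
            layer = clf.assign_layer(u.depth_um)
        else:
            tag, layer = "not_tagged", "outside"
        classifications[u.unit_id] = clf.UnitClassification(
            unit_id=u.unit_id,
            tagged=tag,
            interneuron=clf.classify_interneuron(u.waveform) if u.waveform else None,
            layer=layer,
            baseline_rate=float(
                len(u) / (session.duration_ms / 1000.0)
            ),
        )

    interneurons = [uid for uid, c in classifications.items() if c.interneuron]
    unclassifiable = [
        uid
        for uid, c in classifications.items()
        if c.tagged == "unclassifiable" and uid not in interneurons
    ]
    analysis_units = [
        u
        for u in session.units
        if u.unit_id not in interneurons and u.unit_id not in unclassifiable
    ]
    if not analysis_units:
        raise PipelineError("classify", "no units survive the exclusion rules")

    # ---------------------------------------------------------------- metrics
    conditions = {"ctrl": "puff_only", "opto": "combined"}
    rows = []
    psths: dict = {}
    for u in analysis_units:
        uclass = _unit_class(u, classifications[u.unit_id].tagged)
        for state in ("quiet", "whisking"):
            for cname, cond in conditions.items():
                sel = ev[
                    (ev["condition"] == cond)
                    & (sweep_state.reindex(ev["sweep_id"]).to_numpy() == state)
                ]
                if len(sel) < ana.min_sweeps_per_cell:
                    raise PipelineError(
                        "metrics",
                        f"only {len(sel)} {state} sweeps in condition {cond}; "
                        "increase sweep counts or relax the state purity window",
                    )
                events = sel["deflection_ms"].to_numpy()
                p = build_psth(
                    u,
                    events,
                    window_ms=ana.psth_window_ms,
                    bin_width_ms=ana.bin_width_ms,
                    alignment="deflection",
                    state_label=state,
                )
                psths.setdefault((uclass, state, cname), []).append((u.unit_id, p))
                m = met.response_metrics(p)
                rows.append(
                    {
                        "unit_id": u.unit_id,
                        "unit_class": uclass,
                        "structure": u.structure,
                        "state": state,
                        "condition": cname,
                        "n_sweeps": len(sel),
                        "spont_rate": window_rate(u, events, ana.spont_window_ms),
                        "wer_rate": window_rate(u, events, ana.wer_window_ms),
                        "onset_latency_ms": m.onset_latency_ms,
                        "peak_rate": m.peak_rate,
                        "peak_time_ms": m.peak_time_ms,
                        "slope_spikes_per_s_per_ms": m.slope,
                        "wer1_rate": m.wer1_rate,
                        "wer2_rate": m.wer2_rate,
                    }
                )
    metrics_df = pd.DataFrame(rows)

    # ------------------------------------------------- ROUT outliers on deltas
    deltas = metrics_df.pivot_table(
        index=["unit_id", "unit_class"], columns=["state", "condition"], values="spont_rate"
    )
    outliers: list[str] = []
    for uclass, grp in deltas.groupby(level="unit_class"):
        d = (grp[("quiet", "ctrl")] - grp[("quiet", "opto")]).to_numpy()
        if d.size >= 3:
            mask = wstats.rout_outliers(d, cfg.analysis.rout_q_percent)
            outliers.extend(grp.index.get_level_values("unit_id")[mask])
    metrics_df = metrics_df[~metrics_df["unit_id"].isin(outliers)].reset_index(drop=True)

    # ---------------------------------------------------------------- summary
    long = metrics_df.melt(
        id_vars=["unit_id", "unit_class", "state", "condition"],
        value_vars=["spont_rate", "wer_rate"],
        var_name="measure",
        value_name="rate",
    )
    long["measure"] = long["measure"].str.replace("_rate", "", regex=False)
    summary = (
        long.groupby(["unit_class", "state", "condition", "measure"])["rate"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n="count")
        .reset_index()
    )

    # ------------------------------------------------------------------ stats
    anova_rows, posthoc_rows = [], []
    for (uclass, state), grp in long.groupby(["unit_class", "state"]):
        table = grp.rename(
            columns={"unit_id": "subject", "measure": "row", "condition": "col", "rate": "value"}
        )
        try:
            res = wstats.two_way_rm_anova(table, design=ana.anova_design)
        except ValueError as e:
            raise PipelineError("stats", f"{uclass}/{state}: {e}") from e
        a = res.table.copy()
        a.insert(0, "state", state)
        a.insert(0, "unit_class", uclass)
        anova_rows.append(a)
        ph = res.posthoc.copy()
        ph.insert(0, "state", state)
        ph.insert(0, "unit_class", uclass)
        posthoc_rows.append(ph)
    anova_df = pd.concat(anova_rows, ignore_index=True)
    posthoc_df = pd.concat(posthoc_rows, ignore_index=True)

    n_units = len(session.units)
    exclusions = {
        "units_in": n_units,
        "interneurons": sorted(interneurons),
        "unclassifiable": sorted(unclassifiable),
        "rout_outliers": sorted(set(outliers)),
        "units_analyzed": int(metrics_df["unit_id"].nunique()),
    }
    log = {
        "seed": cfg.seed,
        "n_sweeps": int(len(ev)),
        "sweep_census": census.to_dict(orient="records"),
        "state_provenance": "classified",
    }
    return PipelineResult(
        summary=summary,
        metrics=metrics_df,
        anova=anova_df,
        posthoc=posthoc_df,
        exclusions=exclusions,
        log=log,
        session=session,
        psths=psths,
    )


def make_report(result: PipelineResult, fig_dir: str | Path) -> list[Path]:
    """Averaged PSTH figures (mean ± SEM across units) per class/state/condition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(fig_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not result.psths:
        raise PipelineError("report", "no PSTHs to plot")
    paths = []
    for (uclass, state, cond), entries in sorted(result.psths.items()):
        rates = np.array([p.rate for _, p in entries])
        edges = entries[0][1].bin_edges
        centers = (edges[:-1] + edges[1:]) / 2.0
        mean = rates.mean(axis=0)
        sem = rates.std(axis=0, ddof=1) / np.sqrt(rates.shape[0]) if rates.shape[0] > 1 else 0 * mean
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.fill_between(centers, mean - sem, mean + sem, alpha=0.3, color="tab:blue")
        ax.plot(centers, mean, color="tab:blue")
        ax.axvline(0.0, color="k", lw=0.5)
        ax.set_xlabel("time from deflection (ms)")
        ax.set_ylabel("rate (spikes/s)")
        ax.set_title(f"{uclass} — {state} — {cond} (n={rates.shape[0]})")
        fname = out / f"psth_{uclass.replace('/', '')}_{state}_{cond}.png".replace("-", "_")
        fig.tight_layout()
        fig.savefig(fname, dpi=100)
        plt.close(fig)
        paths.append(fname)
    return paths
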