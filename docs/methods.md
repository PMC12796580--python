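# Methods

This note documents the models, parameter choices and numerical conventions
behind `whiskloop`, and what the synthetic-data validation does and does not
establish about real recordings.

## Synthetic sessions

**Protocol.** A session consists of blocks of sweeps for three stimulation
conditions — light pulse only, air puff only, and both combined — delivered in
a seed-determined random order within each cycle.  Defaults: 30 sweeps per
condition, 2 cycles, sweeps at 0.5 Hz (2 s apart), 20 ms air puffs whose air
travel adds a 10 ms delay between trigger and deflection at the whiskers, and
a 70 ms light pulse starting 50 ms before the deflection (so the pulse ends
with the puff).  Nominal light and deflection times are recorded for every
sweep regardless of condition, so any sweep can serve as an alignment
reference; whether the stimulus was actually delivered is given by the
condition column.  The deflection-at-whisker time is the alignment zero for
all evoked analysis — evoked latencies of a few milliseconds are only
physically meaningful relative to air arrival, not to the trigger — and
trigger- or light-aligned analysis remains available through the alignment
argument.

**Behavioural states.** Quiet and whisking bouts alternate with
exponentially distributed durations (means 3 s quiet / 2 s whisking, clipped
below at 500 ms).  Bout statistics for head-restrained mice are not tightly
constrained; these values produce sessions in which both states contribute
tens of sweeps per condition, which is what the downstream designs need.

**Firing model.** Each unit is an inhomogeneous Poisson process

    r(t) = base_rate · m_state(t) · m_opto(t) + Σ_d wer_amplitude · k(t − t_d)

with `m_state = whisking_multiplier` inside whisking bouts (default 2, the
magnitude of state modulation typical of these structures), and
`m_opto = opto_suppression ∈ [0, 1]` inside `[light_on + latency, light_off]`
of light sweeps.  The photo-suppression multiplies only the background term;
the evoked transient is additive.  The evoked kernel `k` rises linearly from
an onset to a peak and decays exponentially afterwards.  An alpha function
was considered but cannot honour independent peak and decay parameters; the
linear-rise/exponential-decay form does, and its integral
`(peak − onset)/2 + decay` makes expected evoked counts available in closed
form for test oracles.  VPM-like units add a second, late component (default
onset 41 ms) of the same form.  Spikes are sampled by thinning against the
explicit rate bound `base·mult + amplitudes`, which is exact for any kernel
shape.  Each unit draws from a sub-stream derived from (session seed,
unit id), so adding a unit never perturbs the others, and a session is
bit-reproducible from its configuration and seed.

**LFP.** Each bout contributes a sum of three sinusoids with frequencies
drawn uniformly from the quiet band (4–12 Hz) or from the union of the
active bands (13–60 Hz), random phases, total oscillation amplitude 1, plus
white noise of SD 0.5.  This is a caricature: real LFPs have 1/f backgrounds,
band power varies continuously, and "active non-whisking" epochs exist that
no purely spectral rule can separate from whisking.  Passing the recovery
tests therefore shows that the classifier implements its stated rule
correctly and robustly at a realistic spectral contrast — not that the rule
resolves every ambiguity of real data, where video-based confirmation remains
the arbiter.

## State segmentation

The spectrogram is a sliding Welch PSD (single Hann-tapered segment per
window).  Defaults: 500 ms windows stepped by 125 ms.  A 500 ms window gives
2 Hz resolution — enough to separate the 4–12 Hz band from 13 Hz upward —
while keeping boundary jitter well below typical bout durations; 1 s windows
were tried first and cost noticeably more boundary time than they bought in
frequency resolution.  Per window the active/quiet ratio
`R = ∫_{13–60} PSD / ∫_{4–12} PSD` (linear power, overlap of the two active
bands counted once) decides the label: whisking if `R > 1.5`, quiet if
`R < 1/1.5`, excluded otherwise — ties go to exclusion, inheriting the
removal rule for ambiguous ("active non-whisking") epochs.  Episodes shorter
than 500 ms are relabelled excluded.  A sweep gets a state only when a single
labelled interval covers its whole analysis window (default −200 to +100 ms
around the deflection); sweeps straddling transitions are excluded, and
excluded time never enters any PSTH denominator.

On default synthetic sessions the classified intervals match ground truth on
≈96% of session time and ≈95% of sweep labels (measured by the acceptance
script); the residual disagreement is concentrated at bout boundaries and in
sub-second bouts, as expected from the window length.

## PSTHs and spike detection

Bins are half-open `[t, t + Δ)` with Δ = 2 ms by default (the binning of the
onset rule); a spike exactly on an edge belongs to the right bin.  Rates are
normalized per sweep: count / n_sweeps / bin width.  All realized
per-state sweep counts — which differ across conditions after state
filtering — are used as denominators and logged per session.

The optional threshold detector band-passes the raw trace at 300–3000 Hz
(4th-order Butterworth, zero-phase) and reports negative-going excursions
beyond 4 SD of the filtered trace, merging crossings within 1 ms.  The SD is
computed over the whole trace — a conservative stand-in for a quiescent
"background" segment, which a generic pipeline cannot identify reliably.

## Unit classification

**Opto-tagging.**  The averaged light-aligned PSTH provides a baseline mean μ
and SD σ from the 200 ms before the pulse and a tag-window rate over the
first 5.5 ms of the pulse (2-ms bins whose start lies before 5.5 ms).  Units
with μ below 1 spike/s are unclassifiable.  The published criterion reads
"lower than the mean + 2 SD", which any quiescent unit satisfies; it is
implemented as μ − 2σ (the literal version stays selectable via
`rule="literal"` so the discrepancy is auditable).  When μ − 2σ ≥ 0 a unit is
tagged iff its tag-window rate is at most that bound and strictly below μ.
At the rates and sweep counts typical here, however, 2-ms baseline bins are
nearly empty, σ is dominated by Poisson counting noise and exceeds μ/2, and
the bound is vacuous.  In that regime the decision falls back to two
conditions: the tag-window rate must not exceed μ plus one Poisson standard
error of the tag-window estimate (no evidence of an evoked increase), and the
rate over the whole pulse must be at most μ/2 (sustained suppression).  An
exact-silence requirement was rejected: with a 2 ms suppression latency the
pre-latency bin alone fires with probability `1 − exp(−0.12·rate)` over 60
sweeps, which caps sensitivity near 0.5; the fallback above recovers
sensitivity and specificity of 1.0 on 50 simulated units at 2–10 spikes/s.
The comparison uses the averaged PSTH, not per-sweep rates (flagged as a
design choice; per-sweep variance is never used).

**Interneurons and layers.** The fast-spiking rule is a strict conjunction —
asymmetry > 0.15, trough-to-peak < 0.3 ms, half-width < 0.2 ms — and flagged
units are excluded from all population analyses.  Depth maps to layer by the
half-open table [65, 320) → L2/3, [320, 540) → L4, [540, 775) → L5,
[775, ∞) → L6.

## Evoked-response metrics

Onset: threshold = baseline mean + 2·SD over the 200 ms (100 bins) before the
stimulus; the onset is the left edge of the first post-stimulus bin that
opens a run of ≥ 5 bins strictly above threshold, or none.  The detector only
scans post-stimulus bins, so it cannot fire during baseline, and it is
translation-equivariant.  Peak: maximum bin between onset and the end of the
100 ms analysis window, earliest bin on ties.  Slope: OLS of bin rate on
bin-center time over [onset, peak], reported in spikes/s per ms (slopes
quoted "in spikes/s" elsewhere are the same number when the time axis is read
in ms; both conventions appear in the metrics table documentation).  The
biphasic split averages rate over 5–40 ms and 41–100 ms windows (bin-center
attribution), optionally baseline-subtracted.  A prolonged 50–150 ms window
is available as an optional third window and is off by default.

## Statistics

The two-factor repeated-measures ANOVA decomposes sums of squares from cell
means; in the both-within design each effect is tested against its own
effect-by-subject interaction, in the mixed design the between factor is
tested against subjects-within-groups and the within terms against their
pooled interaction.  Both designs exist because experimental descriptions of
this layout alternate between them; the choice is a per-analysis flag.  No
sphericity correction is applied — every within factor in the produced
designs has two levels, where sphericity holds trivially.  Post-hoc
comparisons are t tests between condition levels within each row level
(paired for the within design), Bonferroni-multiplied by the number of row
levels.  Degenerate inputs follow a fixed convention: zero error variance
with zero effect reports F = 0, p = 1; t tests on identical samples report
t = 0, p = 1.

ROUT-style outlier removal covers the one-sample case (difference scores per
unit), which is how it is used here: residuals from the median, robust scale
from the 68.27th percentile of absolute residuals with a √(n/(n−1))
small-sample correction, per-point t p-values, and a Benjamini–Hochberg sweep
at rate Q (default 1%).  Flags are invariant to affine rescaling; exact
numerical agreement with proprietary implementations is out of scope.  The
linear-trend contrast uses evenly spaced centered coefficients on group means
against the pooled within-group mean square.

## Pipeline and problem sizes

`run_pipeline` chains simulate → segment → classify → quantify → test,
applying exclusions in order (interneurons, unclassifiable units, ROUT
outliers on per-unit quiet-state difference scores) with exact accounting:
units in = analyzed + interneurons + unclassifiable + outliers.  Spontaneous
rates use the 50 ms from light onset to deflection; evoked rates the 100 ms
after deflection.  The default run (180 sweeps, 42 units) completes in a few
seconds; the acceptance script's full battery — including a 1000-replicate
null calibration of the paired test on simulated spike trains — runs in well
under a minute on one CPU.  These sizes were chosen so that every recovery
check has enough exposure for its configured confidence interval while the
whole suite stays interactive.

## Known limitations

- The spectral state rule cannot represent "active non-whisking" as a
  positive class; it only routes ambiguity into exclusion.
- The LFP and waveform-feature models are deliberately minimal (no 1/f
  background, no raw per-spike voltage synthesis); tests validate analysis
  logic, not biophysics.
- Mixed-design ANOVA assumes each subject appears in exactly one group;
  unbalanced group sizes are supported, unbalanced within-cells are not.
- ROUT is location-only; regression-based variants are not implemented.
- NWB import/export is not provided; sessions exchange through the
  documented CSV directory layout.
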