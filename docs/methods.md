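# Methods

This note documents the models, conventions and design choices behind the
package; it is the reference for anyone who needs to know exactly what
each number means.

## Conventions

All times are seconds from recording start; all analysis windows are
half-open `[t0, t1)`; Vm is in mV. Vm traces are sampled at 20 kHz by
default (the lick sensor may use its own rate). Recordings are stored
uncorrected for the liquid junction potential, with a metadata flag.

## Behavior

**Lick detection.** A tongue–spout contact is the first sample of a
supra-threshold excursion of the sensor trace; excursions that begin less
than 50 ms after the previous excursion ends are treated as sensor bounce
and merged. The default threshold is the midpoint between the 5th and
95th percentile of the trace — a robust choice for a bimodal
contact/no-contact signal — and both threshold and debounce are
configurable, since sensor mechanics vary between rigs.

**Trial parsing.** Test trials are hits iff a lick falls in
`[stim, stim + 1 s)`; catch trials are false alarms under the same window
around the virtual stimulus time. Reaction time is first contact minus
stimulus onset. The task scheduler aborts trial attempts preceded by
licking within 2 s; the parser assumes delivered streams respect this and
counts violations with a warning rather than re-deciding outcomes.

**Performance.** `d' = Φ⁻¹(HR) − Φ⁻¹(FAR)`. Rates measured as exactly 0
or 1 are replaced by `1/(2N)` or `1 − 1/(2N)` before the quantile, with N
the trial count of the rate being corrected (the per-rate convention of
the signal-detection literature). Recordings gate into *good performer*
(d' > 1.1), *naive* (d' < 0.9), or *indeterminate* (excluded). d' is
always computed over all trials of a recording.

## Subthreshold Vm

**Spike detection** (parameters in `preprocess:`): a spike is the peak of
a contiguous excursion above the session median Vm + 25 mV whose rising
slope, measured over a 0.2 ms span, exceeds 10 mV/ms; accepted peaks are
at least 2 ms apart, so doublets tighter than the refractory window count
once (documented limitation). The 0.2 ms slope span makes the derivative
estimate robust to sample-to-sample recording noise.

**AP removal**: centered running median, default window 8 ms (161 samples
at 20 kHz) — long enough to reject a 1–2 ms action potential entirely,
short relative to the synaptic depolarizations of interest. Edges use
edge-repeating reflection. A running median flattens sharp extrema, so
the filtered peak of a fast PSP sits a few percent below the unfiltered
peak; this attenuation is part of the estimator and is applied equally to
the ground truth in recovery tests (below).

**Evoked metrics**, computed on the trial-averaged filtered trace:
baseline Vm is the mean over `[-5 ms, 0)`; PSP amplitude is the peak over
the early window minus baseline, with the peak search bounded to
`(0, 50 ms]` so the slower secondary depolarization cannot masquerade as
the sensory response (the bound is configurable); ΔVm late / lick are the
window means over `[0.05, 0.25)` / `[0.25, 1.0)` s minus baseline, with
the alternative `[0.05, 0.35)` / `[0.35, 1.0)` split also reported.
Evoked AP rates in the early/late/lick windows are baseline-subtracted
and may be negative. The spontaneous (baseline) AP rate pools the 2-s
windows preceding each trial that contain no lick; totals under 16 s are
flagged low-confidence. PSTHs use 50 ms (or 10 ms) half-open bins and are
displayed baseline-subtracted.

**Aggregation** is cell-by-cell by default; at the mouse level cells are
first averaged within each mouse so every mouse carries equal weight.

## Spontaneous licking

Bouts are maximal lick runs with inter-lick intervals under 1 s — the gap
matches the time scale of the "1 s after cessation" selection rule, since
no separate bout definition is standard. A bout is analyzed when its
onset is ≥ 3 s after the most recent preceding whisker stimulus (future
stimuli do not disqualify) and ≥ 1 s after the previous bout's offset.
ΔVm is the aligned-average mean over `[-0.1, +0.1)` s minus the baseline
mean over `[-1.0, -0.6)` s; ΔAP is the analogous rate difference.

**Pre-lick onset.** Scanning from −0.6 s (the end of the baseline window)
to the lick onset, the onset is the first time the aligned mean exceeds
baseline mean + 3×SD *and stays above threshold for ≥ 50 ms*. The
persistence requirement makes the 3×SD rule robust to brief noise
excursions; the SD is taken from the cell's mean aligned trace over the
baseline window (not across bouts), and a degenerate zero SD falls back
to an absolute 0.5 mV offset, flagged. Cells that never cross are
reported as lacking a pre-lick depolarization.

## Statistics

Unpaired comparisons use the two-tailed Wilcoxon rank-sum test (exact
null when `n1·n2 ≤ 400` with no ties, else the normal approximation with
tie and continuity corrections); paired comparisons use the two-tailed
signed-rank test (zero differences dropped; exact for n ≤ 25 without
ties). Degenerate inputs (identical samples, all-zero differences) report
p = 1 with a flag rather than erroring. Box summaries use linear
(type-7) quartile interpolation and Tukey whiskers (most extreme data
within 1.5×IQR of the quartiles). Raw p-values are reported without
multiple-testing correction — the comparisons form a small confirmatory
design — and the report footer states this.

## Synthetic sessions

The generator emulates the statistical structure the analysis assumes; it
is a measurement testbed, not a biophysical model.

**Scheduler and behavior.** Trial attempts at Uniform(2, 10) s intervals;
catch probability 0.45 (validated to the 40–50% design range); attempts
preceded by licking within 2 s are aborted and rescheduled. Delivered
test (catch) trials elicit a response bout with probability `p_hit`
(`p_fa`); response latency is a shifted Gamma with mean 317 ms and SD
100 ms for trained presets (369 ms for naive), truncated to
(0.05 s, reward window). Spontaneous bouts arrive as a thinned Poisson
process (3.5 bouts/min, ~6 Hz licking, ~1 s duration, chosen to yield
bout counts comparable to a trained recording). Generation is closed
loop: the abort check sees all licks generated so far, and spontaneous
bouts whose first lick would fall inside a delivered reward window (or
merge with a response bout) are removed — in the real task such licks
*are* the response, already accounted for by `p_hit`/`p_fa`. This makes
the scheduler log and the parser's classification provably consistent,
which the tests assert exactly.

**Vm model.**
`vm = rest + OU + Σ PSP + Σ late + Σ lick-ramp + white noise + spikes`:

- PSP: difference of exponentials (τ_rise 2 ms, τ_decay 30 ms),
  peak-normalized so the per-trial amplitude parameter
  (Normal, floored at 0) is the true peak;
- late component: raised-cosine bump peaking 261 ms after the stimulus
  (width 0.3 s) on hit trials, scaled by 0.3 on misses — the miss-trial
  amplitude is exposed as a scale factor because only the qualitative
  pattern (smaller late depolarization on misses) is constrained;
- lick ramp: linear rise starting 260 ms before each bout's first
  contact, plateau over the bout, 0.3 s linear decay;
- background: stationary Ornstein–Uhlenbeck process, τ = 100 ms,
  σ = 2 mV (slow network fluctuation scale), plus 0.3 mV white noise;
- spikes: inhomogeneous Poisson with rate
  `r₀·exp(gain·(Vm_sub − rest))` capped at 100 Hz (r₀ = 0.3 Hz,
  gain = 0.25 /mV), 3 ms refractory, each adding a stereotyped 1 ms,
  45 mV Gaussian waveform.

Group × projection-target presets set response probabilities (0.77/0.17
trained, 0.31/0.28 naive) and kernel amplitudes so default cohorts show
the qualitative trained-vs-naive, S2-p-vs-M1-p effect pattern.

**What the simulator does not capture:** correlated trial-to-trial state
changes, non-stationary drift, electrode artifacts, true spike waveform
diversity, bursting, and any orofacial movement signal. Passing recovery
tests therefore demonstrates correctness of the measurement code under
the assumed statistics, not robustness to every failure mode of real
recordings.

**Ground truth for recovery tests** is the noiseless limit of the
pipeline: the metrics of the deterministic subthreshold signal (kernels
only, no noise, no spikes) passed through the same AP-removal filter and
window arithmetic. This isolates the error caused by noise, spiking and
finite trial counts from the deterministic peak attenuation of the
median filter, which affects truth and estimate identically. The raw
kernel parameters are stored alongside for reference.

**Reproducibility:** per-session RNG substreams are spawned from the
master seed by counter, so cohorts are bit-reproducible and partial
regeneration preserves the remaining sessions.

## Problem sizes in the shipped tests

The validation suite runs entirely on generated data: unit fixtures use
60–120 s sessions; the parameter-recovery check uses 20 trained S2-p
cells with 550 s sessions (≈ 30 hit trials and ≈ 25 selected bouts per
cell), where group-mean recovery of PSP amplitude and ΔVm metrics is
required within 0.5 mV and spike detection within 1% of perfect; test
calibration uses 10,000 Gaussian-null replicates at the cohort sizes
(31 vs 22 unpaired, 19 paired). `scripts/acceptance.py` uses 300 s
sessions (8 + 6 trained, 5 + 5 naive cells), sizes chosen to keep a full
reproduction run around half a minute; estimates scale as expected if
sessions or cohorts are enlarged.

## Known limitations

- The bounded PSP peak search assumes the sensory PSP peaks within 50 ms;
  pathologically slow responses would need the window widened.
- Percent-change summaries (hit vs miss) divide by the miss-trial mean
  and are unstable when that mean is near zero; the mV difference is the
  robust summary at small cohort sizes.
- The sweep-concatenation reader assumes contiguous sweeps (no
  acquisition gaps).
- d' is computed over whole recordings; within-session performance drift
  is not modeled or estimated.
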