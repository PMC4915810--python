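"""Synthetic whole-cell sessions with known ground truth.

Generates complete sessions — trial scheduling, licking behavior, and a
20 kHz membrane-potential trace — with the statistical structure the
analysis assumes, so every pipeline stage can be validated without real
recordings.

The behavioral simulator reproduces the task contingencies: trials at
random 2–10 s intervals, 40–50% catch probability, a 2 s abort-lookback
rule (a trial attempt preceded by licking is aborted and rescheduled), a
1 s reward window, and response probabilities / reaction-time
distributions set per training group. Spontaneous lick bouts form a
thinned Poisson process.

The Vm model is phenomenological, built for testing the measurement code
rather than for biophysical realism:

``vm = rest + OU + Σ PSP kernels + Σ late kernels + Σ lick ramps
      + white noise + spike waveforms``

with a difference-of-exponentials PSP (peak-normalized so the amplitude
parameter is the true peak), a raised-cosine "late" depolarization peaking
261 ms after the stimulus on hit trials (scaled down on misses), a linear
pre-lick ramp starting 260 ms before each bout's first contact that
plateaus over the bout, slow Ornstein-Uhlenbeck background fluctuations,
and spikes drawn from an inhomogeneous Poisson process whose rate grows
exponentially with subthreshold depolarization, each adding a stereotyped
brief waveform.

Every session records a :class:`GroundTruth`: the full scheduler log
(including aborted attempts and virtual catch-stimulus times), per-trial
PSP amplitudes, true spike times, true bout onsets, and the per-cell
evoked/lick metrics of the noise-free subthreshold signal (computed with
the same windows and AP-removal filter the pipeline applies, i.e. the
noiseless limit of the pipeline output — the natural recovery target).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _signal

from . import evoked_analysis, lick_analysis, vm_preprocess
from .session_io import SessionRecording, write_session


# ---------------------------------------------------------------------------
# Configuration

@dataclass
class PSPConfig:
    """Fast sensory PSP: difference of exponentials, peak-normalized."""

    amp_mean_mv: float = 8.0
    amp_sd_mv: float = 2.0
    tau_rise_s: float = 0.002
    tau_decay_s: float = 0.030


@dataclass
class LateComponentConfig:
    """Slow secondary depolarization on hit trials (raised cosine)."""

    amp_mv: float = 4.0
    peak_time_s: float = 0.261
    width_s: float = 0.3
    miss_scale: float = 0.3  # misses carry a partial late component


@dataclass
class LickRampConfig:
    """Lick-related depolarization: linear rise before the first contact,
    plateau over the bout, linear decay after the last contact."""

    amp_mv: float = 3.5
    lead_time_s: float = 0.26
    decay_s: float = 0.3


@dataclass
class SpikeModelConfig:
    """Rate-model spiking: Poisson rate grows exponentially with
    depolarization; each spike adds a stereotyped brief waveform."""

    rate_at_rest_hz: float = 0.3
    gain_per_mv: float = 0.25
    max_rate_hz: float = 100.0
    refractory_s: float = 0.003
    waveform_amp_mv: float = 45.0
    waveform_width_s: float = 0.001


@dataclass
class SimulationConfig:
    """All tunables of one simulated session.

    Scheduler fields implement the task contingencies (2–10 s ITIs,
    40–50% catch trials, 2 s abort lookback, 1 s reward window).
    Behavioral defaults are the trained-mouse operating point (hit rate
    0.77, false-alarm rate 0.17, mean reaction time 317 ms); group/target
    presets are available via :func:`preset_config`.
    """

    session_duration_s: float = 1200.0
    sample_rate_hz: float = 20000.0
    sample_rate_lick_hz: float = 5000.0
    iti_range_s: tuple = (2.0, 10.0)
    catch_fraction: float = 0.45
    abort_lookback_s: float = 2.0
    reward_window_s: float = 1.0
    p_hit: float = 0.77
    p_fa: float = 0.17
    rt_mean_s: float = 0.317
    rt_sd_s: float = 0.10
    rt_min_s: float = 0.05
    spontaneous_bout_rate_per_min: float = 3.5
    bout_lick_rate_hz: float = 6.0
    bout_duration_mean_s: float = 1.0
    bout_duration_min_s: float = 0.3
    vm_rest_mv: float = -60.0
    ou_tau_s: float = 0.1
    ou_sigma_mv: float = 2.0
    noise_sigma_mv: float = 0.3
    psp: PSPConfig = field(default_factory=PSPConfig)
    late: LateComponentConfig = field(default_factory=LateComponentConfig)
    lick_ramp: LickRampConfig = field(default_factory=LickRampConfig)
    spikes: SpikeModelConfig = field(default_factory=SpikeModelConfig)

    def __post_init__(self):
        if not (0.4 <= self.catch_fraction <= 0.5):
            raise ValueError("catch_fraction must lie in [0.4, 0.5]")
        if self.lick_ramp.lead_time_s <= 0:
            raise ValueError("lick_ramp.lead_time_s must be positive")
        for name in ("session_duration_s", "sample_rate_hz",
                     "reward_window_s", "rt_mean_s",
                     "spontaneous_bout_rate_per_min", "bout_lick_rate_hz",
                     "bout_duration_mean_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.p_hit <= 1 and 0 <= self.p_fa <= 1):
            raise ValueError("p_hit and p_fa must be probabilities")


#: Group x projection-target presets: response statistics follow the two
#: training groups' operating points; kernel amplitudes are set so the
#: default cohorts show the qualitative effect pattern of trained vs naive
#: mice (strong late/lick depolarization in trained S2-p cells, stronger
#: PSPs and lick-phase depolarization in naive M1-p cells).
_PRESETS = {
    ("good_performer", "S2-p"): dict(
        p_hit=0.77, p_fa=0.17, rt_mean_s=0.317,
        psp=dict(amp_mean_mv=7.0), late=dict(amp_mv=4.0),
        lick_ramp=dict(amp_mv=3.5)),
    ("good_performer", "M1-p"): dict(
        p_hit=0.77, p_fa=0.17, rt_mean_s=0.317,
        psp=dict(amp_mean_mv=7.5), late=dict(amp_mv=1.7),
        lick_ramp=dict(amp_mv=0.8)),
    ("naive", "S2-p"): dict(
        p_hit=0.31, p_fa=0.28, rt_mean_s=0.369,
        psp=dict(amp_mean_mv=8.4), late=dict(amp_mv=0.4),
        lick_ramp=dict(amp_mv=0.5)),
    ("naive", "M1-p"): dict(
        p_hit=0.31, p_fa=0.28, rt_mean_s=0.369,
        psp=dict(amp_mean_mv=12.2), late=dict(amp_mv=1.5),
        lick_ramp=dict(amp_mv=2.2)),
}


def preset_config(group: str, projection_target: str,
                  **overrides) -> SimulationConfig:
    """A SimulationConfig for one training group x projection target."""
    base = _PRESETS[(group, projection_target)]
    kwargs = {}
    for key, val in base.items():
        if isinstance(val, dict):
            cls = {"psp": PSPConfig, "late": LateComponentConfig,
                   "lick_ramp": LickRampConfig}[key]
            kwargs[key] = cls(**val)
        else:
            kwargs[key] = val
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    schedule: pd.DataFrame          # every attempt incl. aborted ones
    psp_amps: dict                  # delivered-test trial time -> true amp
    spike_times: np.ndarray
    bouts: pd.DataFrame             # onset, offset, kind (response/spont)
    true_metrics: dict              # noiseless-limit per-cell metrics
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Behavioral event generation

class _BoutList:
    """Lick bouts with lazy removal, queryable by time interval."""

    def __init__(self):
        self.licks: list[np.ndarray] = []
        self.kinds: list[str] = []
        self.alive: list[bool] = []

    def add(self, licks, kind):
        self.licks.append(np.asarray(licks, dtype=float))
        self.kinds.append(kind)
        self.alive.append(True)

    def any_lick_in(self, lo, hi) -> bool:
        for lk, ok in zip(self.licks, self.alive):
            if ok and lk[-1] >= lo and lk[0] < hi:
                if np.any((lk >= lo) & (lk < hi)):
                    return True
        return False

    def drop_with_first_lick_in(self, lo, hi):
        for i, (lk, ok) in enumerate(zip(self.licks, self.alive)):
            if ok and self.kinds[i] == "spontaneous" and lo <= lk[0] < hi:
                self.alive[i] = False

    def table(self) -> pd.DataFrame:
        rows = [
            {"onset": lk[0], "offset": lk[-1], "kind": kind}
            for lk, kind, ok in zip(self.licks, self.kinds, self.alive)
            if ok
        ]
        df = pd.DataFrame(rows, columns=["onset", "offset", "kind"])
        return df.sort_values("onset", ignore_index=True)

    def all_licks(self) -> np.ndarray:
        parts = [lk for lk, ok in zip(self.licks, self.alive) if ok]
        return (np.sort(np.concatenate(parts)) if parts
                else np.empty(0))


def _draw_bout_licks(cfg: SimulationConfig, rng, onset: float) -> np.ndarray:
    """Lick contact times of one bout starting at ``onset``."""
    duration = cfg.bout_duration_min_s + rng.exponential(
        max(cfg.bout_duration_mean_s - cfg.bout_duration_min_s, 1e-3))
    mean_ili = 1.0 / cfg.bout_lick_rate_hz
    times = [onset]
    t = onset
    while True:
        ili = max(0.04, rng.normal(mean_ili, 0.2 * mean_ili))
        t += ili
        if t - onset > duration:
            break
        times.append(t)
    return np.asarray(times)


def _draw_reaction_time(cfg: SimulationConfig, rng) -> float:
    """Shifted-gamma latency truncated to (rt_min, reward window)."""
    mean = cfg.rt_mean_s - cfg.rt_min_s
    shape = (mean / cfg.rt_sd_s) ** 2
    scale = cfg.rt_sd_s ** 2 / mean
    for _ in range(1000):
        rt = cfg.rt_min_s + rng.gamma(shape, scale)
        if cfg.rt_min_s < rt < cfg.reward_window_s:
            return rt
    return min(max(cfg.rt_mean_s, cfg.rt_min_s * 1.1),
               cfg.reward_window_s * 0.9)


def schedule_trials(cfg: SimulationConfig, rng, lick_times=(),
                    session_duration_s: float | None = None) -> pd.DataFrame:
    """Draw trial attempts against a fixed lick stream.

    Attempts are spaced by Uniform(2, 10) s intervals; each is a catch
    trial with probability ``catch_fraction``. An attempt preceded by a
    lick within ``abort_lookback_s`` is logged as aborted (and the next
    attempt is scheduled after a fresh interval). Catch trials carry their
    virtual stimulus time. Raises if the session is too short for a single
    attempt.
    """
    duration = session_duration_s or cfg.session_duration_s
    licks = np.sort(np.asarray(lick_times, dtype=float))
    margin = cfg.reward_window_s + 2.0
    rows = []
    t = 0.0
    trial_id = 0
    while True:
        t += rng.uniform(*cfg.iti_range_s)
        if t > duration - margin:
            break
        kind = "catch" if rng.random() < cfg.catch_fraction else "test"
        lo = np.searchsorted(licks, t - cfg.abort_lookback_s)
        hi = np.searchsorted(licks, t)
        aborted = hi > lo
        rows.append({"trial_id": trial_id, "time": t, "type": kind,
                     "aborted": aborted})
        trial_id += 1
    if not rows:
        raise ValueError("session too short to schedule a single trial")
    return pd.DataFrame(rows)


def generate_behavior(cfg: SimulationConfig, rng,
                      schedule: pd.DataFrame) -> dict:
    """Response licking for a fixed schedule (open loop).

    Each delivered test trial elicits a response bout with probability
    ``p_hit`` (catch trials: ``p_fa``) at a shifted-gamma latency; the
    water valve opens at the first lick of each hit. Returns the outcome-
    annotated schedule, response lick times and valve times. Spontaneous
    bouts and abort feedback are handled by :func:`generate_session_events`,
    which runs this logic closed-loop.
    """
    sched = schedule.copy()
    outcomes, rts, licks, valves = [], [], [], []
    for row in sched.itertuples():
        if row.aborted:
            outcomes.append(None)
            rts.append(np.nan)
            continue
        p = cfg.p_hit if row.type == "test" else cfg.p_fa
        if rng.random() < p:
            rt = _draw_reaction_time(cfg, rng)
            bout = _draw_bout_licks(cfg, rng, row.time + rt)
            licks.append(bout)
            rts.append(rt)
            if row.type == "test":
                outcomes.append("hit")
                valves.append(bout[0])
            else:
                outcomes.append("false_alarm")
        else:
            outcomes.append("miss" if row.type == "test"
                            else "correct_rejection")
            rts.append(np.nan)
    sched["outcome"] = outcomes
    sched["reaction_time"] = rts
    lick_times = (np.sort(np.concatenate(licks)) if licks else np.empty(0))
    return {"schedule": sched, "response_licks": lick_times,
            "valve_times": np.asarray(valves), "response_bouts": licks}


def generate_session_events(cfg: SimulationConfig, rng,
                            session_duration_s: float | None = None) -> dict:
    """Closed-loop behavioral stream for one session.

    Spontaneous bouts are drawn first as a Poisson process (thinned so
    consecutive bouts stay separated); trials are then scheduled
    sequentially, checking the abort rule against *all* licks generated so
    far (spontaneous and earlier responses). To keep the generator's trial
    labels and the parser's classification consistent, spontaneous bouts
    whose first lick falls inside a delivered trial's reward window — or
    that would merge with a response bout — are removed: in the real task
    such licks are the response and are already accounted for by
    p_hit/p_fa.
    """
    duration = session_duration_s or cfg.session_duration_s
    bouts = _BoutList()

    # spontaneous bouts: Poisson onsets, >= 1.3 s separation after offsets
    rate = cfg.spontaneous_bout_rate_per_min / 60.0
    t = 3.0
    last_offset = -np.inf
    while True:
        t += rng.exponential(1.0 / rate)
        if t > duration - 3.0:
            break
        if t - last_offset < 1.3:
            continue
        licks = _draw_bout_licks(cfg, rng, t)
        licks = licks[licks < duration - 1.5]
        if licks.size:
            bouts.add(licks, "spontaneous")
            last_offset = licks[-1]

    margin = cfg.reward_window_s + 2.0
    rows = []
    valves = []
    t = 0.0
    trial_id = 0
    while True:
        t += rng.uniform(*cfg.iti_range_s)
        if t > duration - margin:
            break
        kind = "catch" if rng.random() < cfg.catch_fraction else "test"
        aborted = bouts.any_lick_in(t - cfg.abort_lookback_s, t)
        outcome = None
        rt = np.nan
        if not aborted:
            p = cfg.p_hit if kind == "test" else cfg.p_fa
            respond = rng.random() < p
            # licks during a delivered window belong to the response model
            bouts.drop_with_first_lick_in(t, t + cfg.reward_window_s)
            if respond:
                rt = _draw_reaction_time(cfg, rng)
                resp = _draw_bout_licks(cfg, rng, t + rt)
                resp = resp[resp < duration - 0.5]
                bouts.add(resp, "response")
                # drop spontaneous bouts that would merge with the response
                # (margin beyond the gap so detector jitter cannot flip the
                # downstream bout-selection rules)
                bouts.drop_with_first_lick_in(
                    t, resp[-1] + lick_analysis.BOUT_GAP_S + 0.15)
                if kind == "test":
                    outcome = "hit"
                    valves.append(resp[0])
                else:
                    outcome = "false_alarm"
            else:
                outcome = ("miss" if kind == "test"
                           else "correct_rejection")
        rows.append({"trial_id": trial_id, "time": t, "type": kind,
                     "aborted": aborted, "outcome": outcome,
                     "reaction_time": rt})
        trial_id += 1
    schedule = pd.DataFrame(rows)
    if schedule.empty:
        raise ValueError("session too short to schedule a single trial")
    return {
        "schedule": schedule,
        "bouts": bouts,
        "lick_times": bouts.all_licks(),
        "valve_times": np.asarray(valves),
        "duration_s": duration,
    }


# ---------------------------------------------------------------------------
# Vm synthesis

def _psp_kernel(cfg: PSPConfig, fs: float) -> np.ndarray:
    t = np.arange(0, 0.3, 1.0 / fs)
    k = np.exp(-t / cfg.tau_decay_s) - np.exp(-t / cfg.tau_rise_s)
    return k / k.max()


def _late_kernel(cfg: LateComponentConfig, fs: float):
    """Raised-cosine bump peaking at ``peak_time_s``; returns (kernel,
    sample offset of its first sample relative to the stimulus)."""
    half = min(cfg.width_s, cfg.peak_time_s - 0.01)
    t = np.arange(-half, half, 1.0 / fs)
    k = 0.5 * (1.0 + np.cos(np.pi * t / half))
    start = int(round((cfg.peak_time_s - half) * fs))
    return k, start

def _add_kernel(trace, start, kernel):
    n = trace.size
    s, e = start, start + kernel.size
    ks, ke = 0, kernel.size
    if s < 0:
        ks, s = -s, 0
    if e > n:
        ke -= e - n
        e = n
    if ke > ks:
        trace[s:e] += kernel[ks:ke]


def _lick_ramp(trace, fs, cfg: LickRampConfig, onset, offset, amp):
    rise_n = int(round(cfg.lead_time_s * fs))
    plat_n = max(int(round((offset - onset) * fs)), 1)
    decay_n = int(round(cfg.decay_s * fs))
    kernel = np.concatenate([
        np.linspace(0.0, amp, rise_n, endpoint=False),
        np.full(plat_n, amp),
        np.linspace(amp, 0.0, decay_n),
    ])
    _add_kernel(trace, int(round((onset - cfg.lead_time_s) * fs)), kernel)


def _ou_process(n, fs, tau, sigma, rng) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck noise via its exact AR(1) form."""
    a = np.exp(-1.0 / (fs * tau))
    w = rng.standard_normal(n) * sigma * np.sqrt(1.0 - a * a)
    x0 = rng.normal(0.0, sigma)
    zi = _signal.lfiltic([1.0], [1.0, -a], [x0])
    x, _ = _signal.lfilter([1.0], [1.0, -a], w, zi=zi)
    return x


def _spike_waveform(cfg: SpikeModelConfig, fs: float) -> np.ndarray:
    sd = cfg.waveform_width_s / 5.0
    t = np.arange(-3 * sd, 3 * sd, 1.0 / fs)
    return cfg.waveform_amp_mv * np.exp(-0.5 * (t / sd) ** 2)


def generate_vm(cfg: SimulationConfig, rng, events: dict):
    """Synthesize the Vm trace for a generated event stream.

    Returns ``(vm, deterministic, spike_times, psp_amps)`` where
    ``deterministic`` is the noise-free, spike-free subthreshold signal
    (resting potential plus all kernels) used for ground-truth metrics.
    """
    fs = cfg.sample_rate_hz
    n = int(round(events["duration_s"] * fs))
    det = np.full(n, cfg.vm_rest_mv)

    psp_k = _psp_kernel(cfg.psp, fs)
    late_k, late_off = _late_kernel(cfg.late, fs)
    sched = events["schedule"]
    delivered = sched[~sched["aborted"]]
    psp_amps = {}
    for row in delivered.itertuples():
        idx = int(round(row.time * fs))
        if row.type == "test":
            amp = max(rng.normal(cfg.psp.amp_mean_mv, cfg.psp.amp_sd_mv), 0.0)
            psp_amps[row.time] = amp
            _add_kernel(det, idx, amp * psp_k)
            late_amp = (cfg.late.amp_mv if row.outcome == "hit"
                        else cfg.late.amp_mv * cfg.late.miss_scale)
            if late_amp:
                _add_kernel(det, idx + late_off, late_amp * late_k)

    for row in events["bouts"].table().itertuples():
        _lick_ramp(det, fs, cfg.lick_ramp, row.onset, row.offset,
                   cfg.lick_ramp.amp_mv)

    ou = _ou_process(n, fs, cfg.ou_tau_s, cfg.ou_sigma_mv, rng) \
        if cfg.ou_sigma_mv > 0 else np.zeros(n)

    sp = cfg.spikes
    rate = np.clip(sp.rate_at_rest_hz
                   * np.exp(sp.gain_per_mv * (det + ou - cfg.vm_rest_mv)),
                   0.0, sp.max_rate_hz)
    candidates = np.flatnonzero(rng.random(n) < rate / fs)
    spike_idx = []
    last = -np.inf
    min_gap = sp.refractory_s * fs
    for i in candidates:
        if i - last >= min_gap:
            spike_idx.append(i)
            last = i
    spike_times = np.asarray(spike_idx, dtype=float) / fs

    vm = det + ou
    if cfg.noise_sigma_mv > 0:
        vm = vm + rng.standard_normal(n) * cfg.noise_sigma_mv
    wf = _spike_waveform(sp, fs)
    wf_lead = wf.size // 2
    for i in spike_idx:
        _add_kernel(vm, i - wf_lead, wf)
    return vm, det, spike_times, psp_amps


def _true_metrics(cfg: SimulationConfig, det: np.ndarray,
                  events: dict) -> dict:
    """Noiseless-limit metrics of the deterministic subthreshold signal.

    The deterministic trace is passed through the same AP-removal median
    filter and window arithmetic the pipeline uses, so the truth is the
    value a perfect recording (no noise, no spikes) would yield.
    """
    fs = cfg.sample_rate_hz
    det_sub = vm_preprocess.remove_spikes_median(det, fs)
    sched = events["schedule"]
    delivered = sched[~sched["aborted"]]
    hits = delivered[(delivered["type"] == "test")
                     & (delivered["outcome"] == "hit")]
    out = {}
    if len(hits):
        matrix, time, _ = evoked_analysis.align_trials(
            det_sub, fs, hits["time"].to_numpy())
        if matrix.shape[0]:
            mean = matrix.mean(axis=0)
            out["psp_amplitude"] = evoked_analysis.psp_amplitude(mean, time)
            out["dvm_late"] = evoked_analysis.delta_vm(
                mean, time, evoked_analysis.LATE_WINDOW)
            out["dvm_lick"] = evoked_analysis.delta_vm(
                mean, time, evoked_analysis.LICK_WINDOW)
            out["n_hit_trials"] = int(matrix.shape[0])
    stim_times = delivered.loc[delivered["type"] == "test",
                               "time"].to_numpy()
    # selection over ALL bouts: a false-alarm response bout is unrewarded
    # licking and passes the rules whenever it is >= 3 s after the last
    # whisker stimulus, exactly as the analysis sees it
    bout_df = events["bouts"].table()
    selected = lick_analysis.select_spontaneous_bouts(
        bout_df[["onset", "offset"]].to_numpy(), stim_times)
    if selected.bout_onsets.size:
        mod = lick_analysis.lick_aligned_modulation(
            det_sub, fs, np.empty(0), selected.bout_onsets)
        out["dvm_lick_onset"] = mod["dvm_mv"]
        out["n_lick_bouts"] = mod["n_bouts"]
    return out


def generate_session(cfg: SimulationConfig, seed_or_rng,
                     meta: dict | None = None):
    """Generate one full session: ``(SessionRecording, GroundTruth)``."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    events = generate_session_events(cfg, rng)
    vm, det, spike_times, psp_amps = generate_vm(cfg, rng, events)

    fs_lick = cfg.sample_rate_lick_hz
    n_lick = int(round(events["duration_s"] * fs_lick))
    lick_trace = np.zeros(n_lick)
    pulse = max(int(round(0.03 * fs_lick)), 1)
    for t in events["lick_times"]:
        i = int(round(t * fs_lick))
        lick_trace[i:i + pulse] = 1.0

    sched = events["schedule"]
    delivered = sched[~sched["aborted"]]
    session = SessionRecording(
        vm_trace=vm,
        lick_trace=lick_trace,
        sample_rate_vm=cfg.sample_rate_hz,
        sample_rate_lick=fs_lick,
        stim_times=delivered.loc[delivered["type"] == "test",
                                 "time"].to_numpy(),
        catch_times=delivered.loc[delivered["type"] == "catch",
                                  "time"].to_numpy(),
        valve_times=np.sort(events["valve_times"]),
        meta=dict(meta or {}, liquid_junction_corrected=False),
    )
    truth = GroundTruth(
        schedule=sched,
        psp_amps=psp_amps,
        spike_times=spike_times,
        bouts=events["bouts"].table(),
        true_metrics=_true_metrics(cfg, det, events),
        config=cfg,
    )
    return session, truth


# ---------------------------------------------------------------------------
# Cohorts

def generate_cohort(cohort_spec, seed: int, out_dir=None,
                    cells_per_mouse: int = 2):
    """Generate a multi-cell cohort with per-session RNG substreams.

    ``cohort_spec`` is a list of dicts with keys ``group``,
    ``projection_target``, ``n_cells`` and optionally ``config`` (a
    SimulationConfig; defaults to the group/target preset). Sessions are
    reproducible: substream seeds are spawned from the master seed by
    counter, so the same seed yields bit-identical cohorts. With
    ``out_dir`` set, sessions are written via the container writer and a
    ``ground_truth.json`` manifest summarizes the per-cell truth.

    Returns a list of records ``{cell_id, mouse_id, group,
    projection_target, session, truth, path}``.
    """
    ss = np.random.SeedSequence(seed)
    total = sum(entry["n_cells"] for entry in cohort_spec)
    children = ss.spawn(total)
    records = []
    k = 0
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for entry in cohort_spec:
        group = entry["group"]
        target = entry["projection_target"]
        cfg = entry.get("config") or preset_config(group, target)
        for i in range(entry["n_cells"]):
            mouse_id = f"{group}_{target}_m{i // cells_per_mouse:02d}"
            cell_id = f"{group}_{target}_c{i:02d}"
            meta = {"mouse_id": mouse_id, "cell_id": cell_id,
                    "projection_target": target, "group": group}
            rng = np.random.default_rng(children[k])
            k += 1
            session, truth = generate_session(cfg, rng, meta=meta)
            rec = {"cell_id": cell_id, "mouse_id": mouse_id, "group": group,
                   "projection_target": target, "session": session,
                   "truth": truth, "path": None}
            if out_dir is not None:
                path = out_dir / f"{cell_id}.h5"
                write_session(session, path)
                rec["path"] = str(path)
            records.append(rec)
    if out_dir is not None:
        manifest = [{
            "cell_id": r["cell_id"], "mouse_id": r["mouse_id"],
            "group": r["group"], "projection_target": r["projection_target"],
            "path": r["path"],
            "true_metrics": {k: (float(v) if np.isscalar(v) else v)
                             for k, v in r["truth"].true_metrics.items()},
            "n_spikes": int(r["truth"].spike_times.size),
        } for r in records]
        with open(out_dir / "ground_truth.json", "w") as f:
            json.dump(manifest, f, indent=1)
    return records
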