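"""End-to-end per-session and cohort analysis.

``analyze_session`` runs the full chain on one recording: lick detection,
trial parsing, performance gating, spike detection and AP removal,
stimulus-evoked metrics (hit and, when available, miss trials),
spontaneous lick-bout selection and lick-aligned modulation.
``analyze_cohort`` assembles the per-cell metrics table and the group
report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior, evoked_analysis, lick_analysis, vm_preprocess
from .config import default_config
from .session_io import SessionRecording, read_session
from .stats_report import build_report


@dataclass
class CellResult:
    """Everything the pipeline computed for one recording."""

    meta: dict
    trials: pd.DataFrame
    performance: behavior.PerformanceSummary
    spike_times: np.ndarray
    baseline_ap: evoked_analysis.BaselineAPRate | None
    evoked_hit: evoked_analysis.EvokedMetrics | None
    evoked_miss: evoked_analysis.EvokedMetrics | None
    lick_bouts: lick_analysis.LickBoutSet | None
    lick_aligned: dict = field(default_factory=dict)
    prelick_latency_s: float | None = None


def analyze_session(session: SessionRecording | str,
                    config: dict | None = None) -> CellResult:
    """Run the full analysis chain on one session (object or file path)."""
    if not isinstance(session, SessionRecording):
        session = read_session(session)
    cfg = config or default_config()
    b, p, e, l = (cfg["behavior"], cfg["preprocess"], cfg["evoked"],
                  cfg["licks"])

    licks = behavior.detect_licks(
        session.lick_trace, session.sample_rate_lick,
        threshold=b["lick_threshold"], debounce_s=b["lick_debounce_s"])
    trials = behavior.build_trial_table(
        session.stim_times, session.catch_times, licks,
        reward_window_s=b["reward_window_s"],
        abort_lookback_s=b["abort_lookback_s"])
    perf = behavior.summarize_performance(trials)

    decomp = vm_preprocess.decompose(
        session.vm_trace, session.sample_rate_vm,
        dvdt_threshold=p["dvdt_threshold"],
        peak_threshold=p["peak_threshold"],
        refractory_s=p["refractory_s"],
        median_window_s=p["median_window_s"])

    trial_times = np.sort(np.concatenate(
        [session.stim_times, session.catch_times]))
    try:
        baseline = evoked_analysis.baseline_ap_rate(
            decomp.spike_times, trial_times, licks.contact_times,
            lookback_s=b["abort_lookback_s"])
    except ValueError as err:
        warnings.warn(f"baseline AP rate unavailable: {err}", stacklevel=2)
        baseline = None

    evoked_hit = evoked_miss = None
    if baseline is not None:
        hit_stims = trials.loc[trials["outcome"] == "hit",
                               "stim_time"].to_numpy()
        miss_stims = trials.loc[trials["outcome"] == "miss",
                                "stim_time"].to_numpy()
        if hit_stims.size:
            evoked_hit = evoked_analysis.compute_evoked_metrics(
                decomp.vm_sub, session.sample_rate_vm, decomp.spike_times,
                hit_stims, baseline, outcome="hit",
                align_window=e["align_window"], psth_bin_s=e["psth_bin_s"])
        if miss_stims.size:
            evoked_miss = evoked_analysis.compute_evoked_metrics(
                decomp.vm_sub, session.sample_rate_vm, decomp.spike_times,
                miss_stims, baseline, outcome="miss",
                align_window=e["align_window"], psth_bin_s=e["psth_bin_s"])

    bouts = lick_analysis.segment_bouts(licks, gap_s=l["bout_gap_s"])
    bout_set = lick_analysis.select_spontaneous_bouts(
        bouts, session.stim_times,
        min_after_stim_s=l["min_after_stim_s"],
        min_after_bout_s=l["min_after_bout_s"])
    lick_aligned = {}
    prelick = None
    if bout_set.bout_onsets.size:
        lick_aligned = lick_analysis.lick_aligned_modulation(
            decomp.vm_sub, session.sample_rate_vm, decomp.spike_times,
            bout_set.bout_onsets)
        bout_set.dvm_lick_onset = lick_aligned["dvm_mv"]
        bout_set.dap_lick_onset = lick_aligned["dap_hz"]
        if lick_aligned["mean_trace"] is not None:
            prelick = lick_analysis.prelick_onset(
                lick_aligned["mean_trace"], lick_aligned["time"])
            bout_set.prelick_onset_latency = prelick

    return CellResult(
        meta=dict(session.meta),
        trials=trials,
        performance=perf,
        spike_times=decomp.spike_times,
        baseline_ap=baseline,
        evoked_hit=evoked_hit,
        evoked_miss=evoked_miss,
        lick_bouts=bout_set,
        lick_aligned=lick_aligned,
        prelick_latency_s=prelick,
    )


def metrics_row(result: CellResult) -> dict:
    """Flatten one CellResult into a per-cell metrics-table row."""
    row = {
        "cell_id": result.meta.get("cell_id"),
        "mouse_id": result.meta.get("mouse_id"),
        "group": result.meta.get("group"),
        "projection_target": result.meta.get("projection_target"),
        "d_prime": result.performance.d_prime,
        "hit_rate": result.performance.hit_rate,
        "false_alarm_rate": result.performance.false_alarm_rate,
        "mean_reaction_time": result.performance.mean_reaction_time,
        "performance_label": result.performance.group_label,
    }
    for metrics, suffix in ((result.evoked_hit, "_hit"),
                            (result.evoked_miss, "_miss")):
        for name in ("psp_amplitude", "dvm_late", "dvm_lick",
                     "dvm_alt_late", "dvm_alt_lick",
                     "ap_early", "ap_late", "ap_lick"):
            row[name + suffix] = (getattr(metrics, name)
                                  if metrics is not None else np.nan)
    row["baseline_ap_rate"] = (result.baseline_ap.rate_hz
                               if result.baseline_ap else np.nan)
    bs = result.lick_bouts
    row["dvm_lick_onset"] = (bs.dvm_lick_onset if bs and
                             bs.dvm_lick_onset is not None else np.nan)
    row["dap_lick_onset"] = (bs.dap_lick_onset if bs and
                             bs.dap_lick_onset is not None else np.nan)
    row["prelick_latency_s"] = (result.prelick_latency_s
                                if result.prelick_latency_s is not None
                                else np.nan)
    return row


def analyze_cohort(sessions, config: dict | None = None,
                   enforce_gating: bool = True):
    """Analyze many sessions and build the cross-group report.

    ``sessions`` is an iterable of SessionRecording objects or file paths.
    With ``enforce_gating`` (default), recordings whose measured d' does
    not confirm their labelled training group are excluded from the
    metrics table, mirroring the performance-gated study design.

    Returns ``(cell_df, report, results)``.
    """
    results = [analyze_session(s, config) for s in sessions]
    rows = []
    for res in results:
        if enforce_gating and res.meta.get("group") is not None:
            if res.performance.group_label != res.meta["group"]:
                warnings.warn(
                    f"cell {res.meta.get('cell_id')}: measured d' "
                    f"{res.performance.d_prime:.2f} fails the "
                    f"{res.meta['group']} gate; excluded", stacklevel=2)
                continue
        rows.append(metrics_row(res))
    cell_df = pd.DataFrame(rows)
    report = build_report(cell_df) if len(cell_df) else None
    return cell_df, report, results
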