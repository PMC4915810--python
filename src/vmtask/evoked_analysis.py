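"""Stimulus-evoked subthreshold and spiking response quantification.

All quantities follow the task's standard window conventions (half-open,
seconds relative to stimulus onset):

* baseline Vm — mean over ``[-0.005, 0)`` (the 5 ms before the stimulus);
* PSP amplitude — peak of the trial-averaged AP-removed trace in the early
  response (search window ``(0, 0.05]``) minus baseline;
* ΔVm late / lick — mean of the averaged trace over ``[0.05, 0.25)`` /
  ``[0.25, 1.0)`` minus baseline (alternative split 0.05–0.35 / 0.35–1.0);
* evoked AP rates — spike rate in the early ``[0, 0.05)``, late
  ``[0.05, 0.25)`` and lick ``[0.25, 1.0)`` windows minus the spontaneous
  (baseline) rate measured from lick-free 2-s pre-trial periods;
* PSTH — per-bin spike rate (50 ms or 10 ms bins) averaged over trials,
  shown baseline-subtracted.

Aggregation is cell-by-cell by default; the mouse level first averages the
cells within each mouse so every mouse weighs equally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats_report import box_stats, signed_rank_test

BASELINE_WINDOW = (-0.005, 0.0)
PSP_SEARCH_WINDOW = (0.0, 0.05)     # (0, 0.05], see psp_amplitude
EARLY_WINDOW = (0.0, 0.05)
LATE_WINDOW = (0.05, 0.25)
LICK_WINDOW = (0.25, 1.0)
ALT_LATE_WINDOW = (0.05, 0.35)
ALT_LICK_WINDOW = (0.35, 1.0)
AP_WINDOWS = {"early": EARLY_WINDOW, "late": LATE_WINDOW, "lick": LICK_WINDOW}


@dataclass
class BaselineAPRate:
    """Spontaneous AP rate from lick-free pre-trial periods."""

    rate_hz: float
    total_s: float
    n_windows: int
    low_confidence: bool


@dataclass
class EvokedMetrics:
    """Per-cell stimulus-locked metrics for one trial outcome."""

    outcome: str
    n_trials_used: int
    baseline_vm: float
    psp_amplitude: float
    dvm_late: float
    dvm_lick: float
    dvm_alt_late: float
    dvm_alt_lick: float
    ap_early: float
    ap_late: float
    ap_lick: float
    baseline_ap_rate: float
    psth: dict = field(default_factory=dict)


def align_trials(
    trace,
    sample_rate: float,
    event_times,
    window=(-1.0, 2.0),
):
    """Event-aligned trial matrix.

    Returns ``(matrix, time, kept)``: ``matrix`` is trials x samples with
    t=0 at the event, ``time`` the common time axis (s, relative), and
    ``kept`` a boolean mask over ``event_times`` — events whose window
    extends past the recording edge are dropped with a warning.
    """
    x = np.asarray(trace, dtype=float).ravel()
    events = np.asarray(event_times, dtype=float).ravel()
    i0 = int(round(window[0] * sample_rate))
    i1 = int(round(window[1] * sample_rate))
    length = i1 - i0
    if length <= 0:
        raise ValueError("empty alignment window")
    centers = np.round(events * sample_rate).astype(int)
    kept = (centers + i0 >= 0) & (centers + i1 <= x.size)
    if not kept.all():
        warnings.warn(
            f"dropped {int((~kept).sum())} trial(s) too close to the "
            "recording edge", stacklevel=2,
        )
    idx = centers[kept][:, None] + np.arange(i0, i1)[None, :]
    matrix = x[idx] if kept.any() else np.empty((0, length))
    time = np.arange(i0, i1) / sample_rate
    return matrix, time, kept


def average_response(matrix, mask=None):
    """Pointwise mean across (optionally filtered) trials of one cell.

    Returns ``(mean_trace, per_trial_matrix)``; with zero trials the mean
    is ``None`` and a warning is issued (well-trained mice may have too few
    misses to analyze).
    """
    m = np.asarray(matrix, dtype=float)
    if mask is not None:
        m = m[np.asarray(mask, dtype=bool)]
    if m.shape[0] == 0:
        warnings.warn("no trials of the requested outcome", stacklevel=2)
        return None, m
    return m.mean(axis=0), m


def _window_mean(trace, time, window, closed_right=False):
    lo, hi = window
    if closed_right:
        mask = (time > lo) & (time <= hi)
    else:
        mask = (time >= lo) & (time < hi)
    return float(np.mean(trace[mask]))


def baseline_vm(mean_trace, time, window=BASELINE_WINDOW) -> float:
    """Mean Vm over the 5 ms immediately before the stimulus."""
    return _window_mean(mean_trace, time, window)


def psp_amplitude(
    mean_trace,
    time,
    baseline_window=BASELINE_WINDOW,
    search_window=PSP_SEARCH_WINDOW,
) -> float:
    """Peak of the averaged trace minus baseline Vm.

    The peak search is restricted to the early response ``(0, 0.05]`` so
    the slower secondary depolarization cannot masquerade as the sensory
    PSP; a flat trace gives 0.
    """
    lo, hi = search_window
    mask = (time > lo) & (time <= hi)
    peak = float(np.max(mean_trace[mask]))
    return peak - _window_mean(mean_trace, time, baseline_window)


def delta_vm(
    mean_trace,
    time,
    window,
    baseline_window=BASELINE_WINDOW,
) -> float:
    """Mean of the averaged trace over ``[w0, w1)`` minus baseline Vm."""
    return (_window_mean(mean_trace, time, window)
            - _window_mean(mean_trace, time, baseline_window))


def baseline_ap_rate(
    spike_times,
    trial_times,
    lick_times,
    lookback_s: float = 2.0,
    min_total_s: float = 16.0,
) -> BaselineAPRate:
    """Spontaneous AP rate from the 2 s preceding each trial.

    Windows ``[t - lookback, t)`` before every (test or catch) trial that
    contain no lick are pooled; the rate is total spikes over total time.
    If less than ``min_total_s`` of clean time accumulates, the estimate is
    flagged low-confidence. No qualifying window at all is an error.
    """
    spikes = np.asarray(spike_times, dtype=float)
    trials = np.asarray(trial_times, dtype=float)
    licks = np.asarray(lick_times, dtype=float)
    if trials.size == 0:
        raise ValueError("need at least one trial for the baseline rate")
    n_spikes = 0
    n_windows = 0
    for t in trials:
        lo = t - lookback_s
        if lo < 0:
            continue
        if np.searchsorted(licks, lo) != np.searchsorted(licks, t):
            continue  # a lick inside the window disqualifies it
        n_spikes += int(np.searchsorted(spikes, t)
                        - np.searchsorted(spikes, lo))
        n_windows += 1
    if n_windows == 0:
        raise ValueError("no lick-free pre-trial windows available")
    total = n_windows * lookback_s
    low = total < min_total_s
    if low:
        warnings.warn(
            f"only {total:.1f} s of lick-free baseline (< {min_total_s:g} s);"
            " spontaneous rate is low-confidence", stacklevel=2,
        )
    return BaselineAPRate(
        rate_hz=n_spikes / total,
        total_s=total,
        n_windows=n_windows,
        low_confidence=low,
    )


def evoked_ap_rates(
    spike_times,
    stim_times,
    baseline_rate_hz: float,
    windows: dict | None = None,
) -> dict:
    """Baseline-subtracted spike rate per response window (Hz).

    Each window ``[w0, w1)`` is relative to stimulus onset; the rate pools
    spikes across trials. Values can be negative when the window rate is
    below the spontaneous rate.
    """
    if windows is None:
        windows = AP_WINDOWS
    spikes = np.asarray(spike_times, dtype=float)
    stims = np.asarray(stim_times, dtype=float)
    out = {}
    for name, (w0, w1) in windows.items():
        count = 0
        for t in stims:
            count += int(np.searchsorted(spikes, t + w1)
                         - np.searchsorted(spikes, t + w0))
        duration = max(len(stims), 1) * (w1 - w0)
        out[name] = count / duration - baseline_rate_hz
    return out


def build_psth(
    spike_times,
    event_times,
    bin_s: float = 0.05,
    window=(-1.0, 2.0),
    baseline_rate_hz: float = 0.0,
) -> dict:
    """Event-aligned spike-rate histogram.

    Bins are half-open ``[edge, edge + bin)`` covering ``window``; the rate
    averages spike counts over events. Returns bin edges, the raw rate and
    the baseline-subtracted rate (the display convention), plus the pooled
    counts (whose sum equals the number of spikes falling in the window).
    """
    spikes = np.asarray(spike_times, dtype=float)
    events = np.asarray(event_times, dtype=float)
    n_bins = int(round((window[1] - window[0]) / bin_s))
    edges = window[0] + bin_s * np.arange(n_bins + 1)
    counts = np.zeros(n_bins, dtype=int)
    for t in events:
        rel = spikes[(spikes >= t + window[0]) & (spikes < t + edges[-1])] - t
        idx = np.floor((rel - window[0]) / bin_s).astype(int)
        np.add.at(counts, np.clip(idx, 0, n_bins - 1), 1)
    n_events = max(len(events), 1)
    rate = counts / (n_events * bin_s)
    return {
        "bin_edges": edges,
        "bin_s": bin_s,
        "counts": counts,
        "rate_hz": rate,
        "rate_minus_baseline_hz": rate - baseline_rate_hz,
        "n_events": len(events),
    }


def compute_evoked_metrics(
    vm_sub,
    sample_rate: float,
    spike_times,
    stim_times,
    baseline: BaselineAPRate,
    outcome: str = "hit",
    align_window=(-1.0, 2.0),
    psth_bin_s: float = 0.05,
) -> EvokedMetrics | None:
    """Full stimulus-locked metric set for one outcome's trials.

    ``stim_times`` are the stimulus onsets of the trials of that outcome.
    Returns ``None`` (with a warning) when no trial survives alignment.
    """
    matrix, time, kept = align_trials(vm_sub, sample_rate, stim_times,
                                      align_window)
    mean_trace, _ = average_response(matrix)
    if mean_trace is None:
        return None
    used_stims = np.asarray(stim_times, dtype=float)[kept]
    rates = evoked_ap_rates(spike_times, used_stims, baseline.rate_hz)
    return EvokedMetrics(
        outcome=outcome,
        n_trials_used=matrix.shape[0],
        baseline_vm=baseline_vm(mean_trace, time),
        psp_amplitude=psp_amplitude(mean_trace, time),
        dvm_late=delta_vm(mean_trace, time, LATE_WINDOW),
        dvm_lick=delta_vm(mean_trace, time, LICK_WINDOW),
        dvm_alt_late=delta_vm(mean_trace, time, ALT_LATE_WINDOW),
        dvm_alt_lick=delta_vm(mean_trace, time, ALT_LICK_WINDOW),
        ap_early=rates["early"],
        ap_late=rates["late"],
        ap_lick=rates["lick"],
        baseline_ap_rate=baseline.rate_hz,
        psth=build_psth(spike_times, used_stims, bin_s=psth_bin_s,
                        window=align_window,
                        baseline_rate_hz=baseline.rate_hz),
    )


def aggregate_cells(
    cell_df: pd.DataFrame,
    value_cols,
    level: str = "cell",
    mouse_col: str = "mouse_id",
) -> pd.DataFrame:
    """Group summary (mean, sem, box stats) at the cell or mouse level.

    At the mouse level the cells of each mouse are averaged first, so a
    mouse contributes equally regardless of its cell count. With a single
    observation the sem is NaN (flagged by a warning).
    """
    if level not in ("cell", "mouse"):
        raise ValueError("level must be 'cell' or 'mouse'")
    df = cell_df
    if level == "mouse":
        df = cell_df.groupby(mouse_col, as_index=False)[list(value_cols)].mean()
    rows = []
    for col in value_cols:
        vals = df[col].dropna().to_numpy(dtype=float)
        n = vals.size
        if n == 0:
            continue
        if n == 1:
            warnings.warn(f"{col}: single observation, sem undefined",
                          stacklevel=2)
        bs = box_stats(vals)
        rows.append({
            "metric": col,
            "level": level,
            "n": n,
            "mean": float(vals.mean()),
            "sem": float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
            "median": bs.median,
            "q1": bs.q1,
            "q3": bs.q3,
            "whisker_lo": bs.whisker_lo,
            "whisker_hi": bs.whisker_hi,
        })
    return pd.DataFrame(rows)


def compare_hit_miss(hit_values, miss_values) -> dict:
    """Paired hit-vs-miss comparison across cells.

    Uses only cells with both outcomes. Reports group means, the percent
    change ``(mean_hit - mean_miss) / mean_miss * 100`` (NaN and flagged
    when the miss mean is 0) and the two-tailed signed-rank test.
    """
    hit = np.asarray(hit_values, dtype=float)
    miss = np.asarray(miss_values, dtype=float)
    if hit.shape != miss.shape:
        raise ValueError("hit and miss values must be paired")
    ok = np.isfinite(hit) & np.isfinite(miss)
    hit, miss = hit[ok], miss[ok]
    if hit.size == 0:
        raise ValueError("no cells with both hit and miss data")
    mh, mm = float(hit.mean()), float(miss.mean())
    if mm == 0.0:
        warnings.warn("miss mean is 0; percent change undefined",
                      stacklevel=2)
        pct = np.nan
    else:
        pct = (mh - mm) / mm * 100.0
    return {
        "n": int(hit.size),
        "mean_hit": mh,
        "mean_miss": mm,
        "percent_change": pct,
        "test": signed_rank_test(hit, miss),
    }
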