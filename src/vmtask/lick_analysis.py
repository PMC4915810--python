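"""Spontaneous lick-bout selection and lick-aligned Vm/AP analysis.

Licking outside the task (no stimulus, no reward) reveals movement-related
membrane-potential dynamics. Bouts are maximal runs of licks separated by
less than a gap (1 s); a bout qualifies as *spontaneous* when its onset is
at least 3 s after the most recent whisker stimulus and at least 1 s after
the previous bout ended. The AP-removed Vm is aligned at bout onsets
(first tongue-spout contact); ΔVm is the mean over ±0.1 s around onset
minus the baseline mean over 1.0–0.6 s before onset, and ΔAP the analogous
baseline-subtracted spike rate. The pre-lick depolarization onset is the
first time the aligned mean exceeds baseline mean + 3×SD and stays above
it, scanning from the end of the baseline window to the lick onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .behavior import LickEventTrain
from .evoked_analysis import align_trials, build_psth

BOUT_GAP_S = 1.0
MIN_AFTER_STIM_S = 3.0
MIN_AFTER_BOUT_S = 1.0
LICK_BASELINE_WINDOW = (-1.0, -0.6)
LICK_ONSET_WINDOW = (-0.1, 0.1)
ONSET_PERSISTENCE_S = 0.05
ONSET_SD_FLOOR_MV = 0.5


@dataclass
class LickBoutSet:
    """Selected spontaneous bout onsets and lick-aligned metrics."""

    bout_onsets: np.ndarray
    n_candidates: int
    dvm_lick_onset: float | None = None
    dap_lick_onset: float | None = None
    prelick_onset_latency: float | None = None
    baseline_window: tuple = LICK_BASELINE_WINDOW
    aligned: dict = field(default_factory=dict)


def segment_bouts(licks: LickEventTrain | np.ndarray,
                  gap_s: float = BOUT_GAP_S) -> np.ndarray:
    """Group licks into bouts; returns an (n, 2) array of (onset, offset).

    A bout is a maximal run of consecutive licks whose inter-lick interval
    is below ``gap_s``; its onset is the first contact and its offset the
    last.
    """
    t = licks.contact_times if isinstance(licks, LickEventTrain) \
        else np.asarray(licks, dtype=float)
    if t.size == 0:
        return np.empty((0, 2))
    breaks = np.flatnonzero(np.diff(t) >= gap_s)
    starts = np.r_[0, breaks + 1]
    ends = np.r_[breaks, t.size - 1]
    return np.column_stack([t[starts], t[ends]])


def select_spontaneous_bouts(
    bouts: np.ndarray,
    stim_times,
    min_after_stim_s: float = MIN_AFTER_STIM_S,
    min_after_bout_s: float = MIN_AFTER_BOUT_S,
) -> LickBoutSet:
    """Keep bouts far from stimuli and from earlier licking.

    A bout passes when (a) its onset is at least ``min_after_stim_s`` after
    the most recent preceding whisker stimulus (bouts before the first
    stimulus pass), and (b) its onset is at least ``min_after_bout_s``
    after the previous bout's offset. Only preceding stimuli matter.
    """
    bouts = np.asarray(bouts, dtype=float).reshape(-1, 2)
    stims = np.asarray(stim_times, dtype=float)
    selected = []
    for i, (onset, _offset) in enumerate(bouts):
        j = np.searchsorted(stims, onset)
        if j > 0 and onset - stims[j - 1] < min_after_stim_s:
            continue
        if i > 0 and onset - bouts[i - 1, 1] < min_after_bout_s:
            continue
        selected.append(onset)
    return LickBoutSet(
        bout_onsets=np.asarray(selected, dtype=float),
        n_candidates=int(bouts.shape[0]),
    )


def lick_aligned_modulation(
    vm_sub,
    sample_rate: float,
    spike_times,
    bout_onsets,
    window=(-1.0, 1.0),
    onset_window=LICK_ONSET_WINDOW,
    baseline_window=LICK_BASELINE_WINDOW,
    psth_bin_s: float = 0.05,
) -> dict:
    """Lick-onset-aligned ΔVm, ΔAP, mean trace and PSTH.

    ``vm_sub`` must already be AP-removed. ΔVm is the mean of the aligned
    average over ``[-0.1, +0.1)`` minus the baseline mean over
    ``[-1.0, -0.6)``; ΔAP is the spike rate in the onset window minus the
    rate in the baseline window, pooled across bouts. Returns an empty,
    flagged result when no bout fits inside the recording.
    """
    onsets = np.asarray(bout_onsets, dtype=float)
    matrix, time, kept = align_trials(vm_sub, sample_rate, onsets, window)
    if matrix.shape[0] == 0:
        warnings.warn("no qualifying lick bouts inside the recording",
                      stacklevel=2)
        return {"n_bouts": 0, "mean_trace": None, "time": time,
                "dvm_mv": np.nan, "dap_hz": np.nan, "psth": None}
    used = onsets[kept]
    mean_trace = matrix.mean(axis=0)
    base_mask = (time >= baseline_window[0]) & (time < baseline_window[1])
    on_mask = (time >= onset_window[0]) & (time < onset_window[1])
    dvm = float(mean_trace[on_mask].mean() - mean_trace[base_mask].mean())

    spikes = np.asarray(spike_times, dtype=float)

    def _rate(w0, w1):
        count = 0
        for t in used:
            count += int(np.searchsorted(spikes, t + w1)
                         - np.searchsorted(spikes, t + w0))
        return count / (len(used) * (w1 - w0))

    dap = _rate(*onset_window) - _rate(*baseline_window)
    base_rate = _rate(*baseline_window)
    return {
        "n_bouts": int(matrix.shape[0]),
        "mean_trace": mean_trace,
        "time": time,
        "dvm_mv": dvm,
        "dap_hz": float(dap),
        "psth": build_psth(spikes, used, bin_s=psth_bin_s, window=window,
                           baseline_rate_hz=base_rate),
    }


def prelick_onset(
    mean_trace,
    time,
    baseline_window=LICK_BASELINE_WINDOW,
    n_sd: float = 3.0,
    persistence_s: float = ONSET_PERSISTENCE_S,
    sd_floor_mv: float = ONSET_SD_FLOOR_MV,
) -> float | None:
    """Latency (s) of the pre-lick depolarization onset, or ``None``.

    Scanning forward from the end of the baseline window to the lick
    onset (t = 0), the onset is the first time the aligned mean exceeds
    baseline mean + ``n_sd``×SD(baseline) and remains above threshold for
    at least ``persistence_s`` (noise robustness); the latency is the time
    before tongue contact, so it is positive. Cells whose trace never
    crosses count as lacking a pre-lick depolarization (``None``). A
    degenerate zero SD falls back to an absolute ``sd_floor_mv`` threshold
    offset, with a warning.
    """
    trace = np.asarray(mean_trace, dtype=float)
    time = np.asarray(time, dtype=float)
    base_mask = (time >= baseline_window[0]) & (time < baseline_window[1])
    if not base_mask.any():
        raise ValueError("baseline window not covered by the aligned trace")
    mu = trace[base_mask].mean()
    sd = trace[base_mask].std()
    if sd * n_sd < 1e-12:
        warnings.warn("zero baseline SD; using absolute threshold floor",
                      stacklevel=2)
        thr = mu + sd_floor_mv
    else:
        thr = mu + n_sd * sd
    scan = (time >= baseline_window[1]) & (time < 0.0)
    idx = np.flatnonzero(scan)
    above = trace[idx] > thr
    dt = time[1] - time[0]
    need = max(1, int(round(persistence_s / dt)))
    run = 0
    for k, a in enumerate(above):
        run = run + 1 if a else 0
        if run == need:
            onset_i = idx[k - need + 1]
            return float(-time[onset_i])
    return None
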