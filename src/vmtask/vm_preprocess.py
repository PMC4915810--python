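"""Action-potential detection and removal from the Vm trace.

Subthreshold analysis requires a spike-free membrane potential. Spikes are
detected as supra-threshold excursions with a fast rising slope and removed
with a centered running median whose window (8 ms by default) comfortably
exceeds the ~1 ms action-potential width, leaving slower synaptic
depolarizations intact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

#: Defaults, overridable via the ``preprocess:`` config section.
DEFAULT_DVDT_THRESHOLD = 10.0     # mV/ms
DEFAULT_PEAK_OFFSET = 25.0        # mV above the session median Vm
DEFAULT_REFRACTORY_S = 0.002
DEFAULT_MEDIAN_WINDOW_S = 0.008
_SLOPE_SPAN_S = 2e-4  # slope measured over 0.2 ms, robust to sample noise


@dataclass
class SubthresholdDecomposition:
    """Detected spikes plus the AP-removed (median-filtered) Vm trace."""

    spike_times: np.ndarray
    vm_sub: np.ndarray
    detection_params: dict = field(default_factory=dict)


def detect_spikes(
    vm_trace,
    sample_rate: float,
    dvdt_threshold: float = DEFAULT_DVDT_THRESHOLD,
    peak_threshold: float | None = None,
    refractory_s: float = DEFAULT_REFRACTORY_S,
) -> np.ndarray:
    """Spike times (s): peaks of fast, large depolarizing excursions.

    A spike is the peak sample of a contiguous excursion above
    ``peak_threshold`` (default: session median Vm + 25 mV) whose rising
    slope — measured over a 0.2 ms span ending at or before the peak —
    exceeds ``dvdt_threshold`` mV/ms. Peaks closer than ``refractory_s`` to
    the previous accepted spike are discarded, so a doublet tighter than
    the refractory window counts once.
    """
    v = np.asarray(vm_trace, dtype=float).ravel()
    if sample_rate < 10000:
        raise ValueError("spike detection requires >= 10 kHz sampling")
    if v.size == 0:
        return np.empty(0)
    if peak_threshold is None:
        peak_threshold = float(np.median(v)) + DEFAULT_PEAK_OFFSET
    above = v > peak_threshold
    if not above.any():
        return np.empty(0)
    k = max(1, int(round(_SLOPE_SPAN_S * sample_rate)))
    dt_ms = k / sample_rate * 1e3
    dvdt = np.empty_like(v)
    dvdt[:k] = 0.0
    dvdt[k:] = (v[k:] - v[:-k]) / dt_ms

    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, v.size]

    lead = int(round(0.001 * sample_rate))  # slope search up to 1 ms back
    peaks = []
    for s, e in zip(starts, ends):
        p = s + int(np.argmax(v[s:e]))
        lo = max(0, s - lead)
        if np.max(dvdt[lo:p + 1]) >= dvdt_threshold:
            peaks.append(p)
    times = np.asarray(peaks, dtype=float) / sample_rate
    kept = []
    last = -np.inf
    for t in times:
        if t - last >= refractory_s:
            kept.append(t)
            last = t
    return np.asarray(kept)


def remove_spikes_median(
    vm_trace,
    sample_rate: float,
    median_window_s: float = DEFAULT_MEDIAN_WINDOW_S,
) -> np.ndarray:
    """Centered running median of the Vm trace (AP removal).

    The window is rounded to an odd number of samples (>= 3); edges use
    edge-repeating reflection padding so the output length equals the
    input length. A window
    shorter than twice the typical 2 ms AP width triggers a warning because
    spikes may survive filtering.
    """
    v = np.asarray(vm_trace, dtype=float).ravel()
    n = int(round(median_window_s * sample_rate))
    if n % 2 == 0:
        n += 1
    n = max(n, 3)
    if median_window_s < 0.004:
        warnings.warn(
            "median window shorter than 2x the typical AP width; "
            "spike remnants may survive filtering",
            stacklevel=2,
        )
    if v.size == 0:
        return v.copy()
    return ndimage.median_filter(v, size=n, mode="reflect")


def decompose(
    vm_trace,
    sample_rate: float,
    dvdt_threshold: float = DEFAULT_DVDT_THRESHOLD,
    peak_threshold: float | None = None,
    refractory_s: float = DEFAULT_REFRACTORY_S,
    median_window_s: float = DEFAULT_MEDIAN_WINDOW_S,
) -> SubthresholdDecomposition:
    """Detect spikes and return them with the AP-removed trace."""
    spikes = detect_spikes(
        vm_trace, sample_rate,
        dvdt_threshold=dvdt_threshold,
        peak_threshold=peak_threshold,
        refractory_s=refractory_s,
    )
    vm_sub = remove_spikes_median(vm_trace, sample_rate, median_window_s)
    return SubthresholdDecomposition(
        spike_times=spikes,
        vm_sub=vm_sub,
        detection_params={
            "dvdt_threshold": dvdt_threshold,
            "peak_threshold": peak_threshold,
            "refractory_s": refractory_s,
            "median_window_s": median_window_s,
        },
    )
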