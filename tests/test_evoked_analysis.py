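import numpy as np
import pandas as pd
import pytest

from vmtask import evoked_analysis as ev

FS = 20000.0


def _time(window=(-1.0, 2.0)):
    i0 = int(round(window[0] * FS))
    i1 = int(round(window[1] * FS))
    return np.arange(i0, i1) / FS


# ---------------------------------------------------------------------------
# alignment and averaging

def test_align_constant_trace_single_stim():
    trace = np.full(int(10 * FS), -60.0)
    m, t, kept = ev.align_trials(trace, FS, [5.0])
    assert m.shape == (1, int(3 * FS))
    assert np.all(m == -60.0)
    assert kept.all()
    assert t[0] == -1.0


def test_align_places_delta_at_relative_time():
    trace = np.zeros(int(10 * FS))
    trace[int(5.1 * FS)] = 1.0  # 0.1 s after the stimulus
    m, t, _ = ev.align_trials(trace, FS, [5.0])
    col = np.flatnonzero(m[0])
    assert t[col[0]] == pytest.approx(0.1)


def test_align_shape_for_trial_matrix():
    trace = np.zeros(int(300 * FS))
    stims = 5.0 + 9.0 * np.arange(30)
    m, _, kept = ev.align_trials(trace, FS, stims)
    assert m.shape == (30, 60000)  # [-1, 2) s at 20 kHz, half-open
    assert kept.all()


def test_align_drops_edge_trials_with_warning():
    trace = np.zeros(int(5 * FS))
    with pytest.warns(UserWarning, match="edge"):
        m, _, kept = ev.align_trials(trace, FS, [0.5, 2.5])
    assert kept.tolist() == [False, True]
    assert m.shape[0] == 1


def test_average_identical_and_symmetric_rows():
    row = np.linspace(0, 1, 100)
    mean, _ = ev.average_response(np.stack([row, row, row]))
    np.testing.assert_allclose(mean, row, atol=1e-15)
    mean, _ = ev.average_response(np.stack([row, -row]))
    np.testing.assert_allclose(mean, 0.0, atol=1e-15)


def test_average_of_zero_trials_is_flagged():
    with pytest.warns(UserWarning, match="no trials"):
        mean, _ = ev.average_response(np.empty((0, 10)))
    assert mean is None


def test_average_recovers_kernel_within_clt_bound(rng):
    t = _time()
    kernel = 4.0 * np.exp(-((t - 0.1) / 0.05) ** 2)
    rows = kernel + rng.normal(0, 2.0, (30, t.size))
    mean, _ = ev.average_response(rows)
    assert np.max(np.abs(mean - kernel)) < 3 * (2.0 / np.sqrt(30)) * 4


# ---------------------------------------------------------------------------
# subthreshold metrics

def test_psp_amplitude_baseline_to_peak():
    t = _time()
    trace = np.full(t.size, -65.0)
    trace[(t > 0.005) & (t < 0.015)] = -57.0
    assert ev.psp_amplitude(trace, t) == pytest.approx(8.0)
    flat = np.full(t.size, -60.0)
    assert ev.psp_amplitude(flat, t) == pytest.approx(0.0)


def test_delta_vm_window_algebra():
    t = _time()
    flat = np.full(t.size, -60.0)
    assert ev.delta_vm(flat, t, ev.LATE_WINDOW) == pytest.approx(0.0)
    step = flat.copy()
    step[(t >= 0.05) & (t < 0.25)] += 4.0
    assert ev.delta_vm(step, t, ev.LATE_WINDOW) == pytest.approx(4.0)
    assert ev.delta_vm(step, t, ev.LICK_WINDOW) == pytest.approx(0.0)


def test_delta_vm_and_psp_invariant_to_constant_offset(rng):
    t = _time()
    trace = rng.normal(-60, 2, t.size)
    for c in (0.0, 7.3, -12.0):
        assert ev.delta_vm(trace + c, t, ev.LICK_WINDOW) == pytest.approx(
            ev.delta_vm(trace, t, ev.LICK_WINDOW), abs=1e-9)
        assert ev.psp_amplitude(trace + c, t) == pytest.approx(
            ev.psp_amplitude(trace, t), abs=1e-9)


# ---------------------------------------------------------------------------
# AP rates

def test_baseline_rate_zero_without_spikes():
    out = ev.baseline_ap_rate([], np.arange(10, 40, 3.0), [])
    assert out.rate_hz == 0.0
    assert not out.low_confidence


def test_baseline_rate_counts_spikes_per_time():
    trials = np.arange(10, 34, 3.0)  # 8 windows x 2 s
    spikes = [9.0, 14.5, 20.1, 27.5]  # all inside some pre-trial window
    out = ev.baseline_ap_rate(spikes, trials, [])
    assert out.total_s == pytest.approx(16.0)
    assert out.rate_hz == pytest.approx(4 / 16.0)


def test_baseline_rate_excludes_windows_with_licks():
    trials = np.array([10.0, 20.0, 30.0])
    licks = np.array([18.5])  # disqualifies the window [18, 20)
    spikes = np.array([9.0, 19.0, 29.0])
    with pytest.warns(UserWarning, match="low-confidence"):
        out = ev.baseline_ap_rate(spikes, trials, licks)
    # hand enumeration: windows [8,10) and [28,30) remain, 2 spikes / 4 s
    assert out.n_windows == 2
    assert out.rate_hz == pytest.approx(0.5)


def test_baseline_rate_requires_a_window():
    with pytest.raises(ValueError, match="no lick-free"):
        ev.baseline_ap_rate([], [10.0], [9.5])


def test_evoked_rates_baseline_subtraction():
    out = ev.evoked_ap_rates([], np.arange(10, 100, 9.0), 0.5)
    assert out == {"early": -0.5, "late": -0.5, "lick": -0.5}
    stims = np.arange(10, 100, 9.0)[:10]
    spikes = stims + 0.02
    out = ev.evoked_ap_rates(spikes, stims, 0.0)
    assert out["early"] == pytest.approx(20.0)
    assert out["late"] == pytest.approx(0.0)


def test_evoked_rates_match_per_spike_oracle(rng):
    stims = np.sort(rng.uniform(5, 200, 20))
    stims = stims[np.r_[True, np.diff(stims) > 2.0]]
    spikes = np.sort(rng.uniform(0, 210, 300))
    got = ev.evoked_ap_rates(spikes, stims, 0.0)
    for name, (w0, w1) in ev.AP_WINDOWS.items():
        count = sum(1 for s in spikes for t in stims
                    if t + w0 <= s < t + w1)
        assert got[name] == pytest.approx(count / (len(stims) * (w1 - w0)))


def test_response_windows_partition_the_first_second(rng):
    """Every spike in (0, 1) s after a stimulus lands in exactly one of
    the early/late/lick windows."""
    stims = np.array([10.0])
    spikes = 10.0 + np.sort(rng.uniform(1e-6, 0.999999, 200))
    counts = {}
    for name, (w0, w1) in ev.AP_WINDOWS.items():
        counts[name] = np.sum((spikes >= 10 + w0) & (spikes < 10 + w1))
    assert sum(counts.values()) == spikes.size


# ---------------------------------------------------------------------------
# PSTH

def test_psth_no_spikes_shows_negative_baseline():
    out = ev.build_psth([], [10.0], baseline_rate_hz=2.0)
    assert np.all(out["rate_minus_baseline_hz"] == -2.0)


def test_psth_single_spike_single_trial():
    out = ev.build_psth([10.07], [10.0], bin_s=0.05)
    nz = np.flatnonzero(out["rate_hz"])
    assert nz.size == 1
    assert out["bin_edges"][nz[0]] == pytest.approx(0.05)
    assert out["rate_hz"][nz[0]] == pytest.approx(20.0)


def test_psth_conserves_spike_count(rng):
    stims = np.array([20.0, 40.0, 60.0])
    spikes = np.sort(rng.uniform(0, 80, 500))
    for bin_s in (0.05, 0.01):
        out = ev.build_psth(spikes, stims, bin_s=bin_s, window=(-1.0, 2.0))
        expected = sum(np.sum((spikes >= t - 1.0) & (spikes < t + 2.0))
                       for t in stims)
        assert out["counts"].sum() == expected


def test_psth_uniform_poisson_is_flat(rng):
    lam = 20.0
    duration = 400.0
    n = rng.poisson(lam * duration)
    spikes = np.sort(rng.uniform(0, duration, n))
    stims = np.arange(5, duration - 5, 2.0)
    out = ev.build_psth(spikes, stims, bin_s=0.05, baseline_rate_hz=lam)
    # per-bin sd ~ sqrt(lam / (n_events * bin)) ~ 1.4 Hz, inflated by the
    # overlap of adjacent alignment windows; bound the max over ~60 bins
    # at 0.4*lam and the average deviation much tighter
    dev = np.abs(out["rate_minus_baseline_hz"])
    assert dev.max() < 0.4 * lam
    assert dev.mean() < 0.15 * lam


# ---------------------------------------------------------------------------
# aggregation

def _cell_df():
    return pd.DataFrame({
        "mouse_id": ["a", "b", "b", "b"],
        "value": [1.0, 2.0, 3.0, 4.0],
    })


def test_single_cell_aggregate_flags_sem():
    df = pd.DataFrame({"mouse_id": ["a"], "value": [2.5]})
    with pytest.warns(UserWarning, match="sem undefined"):
        out = ev.aggregate_cells(df, ["value"])
    assert out.loc[0, "mean"] == 2.5
    assert np.isnan(out.loc[0, "sem"])


def test_mouse_level_weights_mice_equally():
    out = ev.aggregate_cells(_cell_df(), ["value"], level="mouse")
    # mouse a -> 1.0, mouse b -> 3.0; equal weights
    assert out.loc[0, "mean"] == pytest.approx(2.0)
    assert out.loc[0, "n"] == 2
    cell = ev.aggregate_cells(_cell_df(), ["value"], level="cell")
    assert cell.loc[0, "mean"] == pytest.approx(2.5)


def test_cell_and_mouse_levels_agree_when_effects_homogeneous(rng):
    mice = np.repeat([f"m{i}" for i in range(17)], 2)[:31]
    df = pd.DataFrame({"mouse_id": mice,
                       "value": rng.normal(3.0, 0.05, 31)})
    cell = ev.aggregate_cells(df, ["value"], level="cell")
    mouse = ev.aggregate_cells(df, ["value"], level="mouse")
    assert cell.loc[0, "mean"] == pytest.approx(mouse.loc[0, "mean"],
                                                abs=0.05)


# ---------------------------------------------------------------------------
# hit vs miss

def test_hit_miss_percent_change_matches_reported_convention():
    # group means 2.63 vs 0.71 mV -> 270% increase after rounding to 10%
    hit = np.full(19, 2.63)
    miss = np.full(19, 0.71)
    out = ev.compare_hit_miss(hit + np.linspace(-0.1, 0.1, 19),
                              miss + np.linspace(-0.05, 0.05, 19))
    assert round(out["percent_change"] / 10) * 10 == 270


def test_hit_miss_degenerate_cases():
    x = np.array([1.0, 2.0, 3.0])
    out = ev.compare_hit_miss(x, x)
    assert out["percent_change"] == pytest.approx(0.0)
    assert out["test"].degenerate
    with pytest.warns(UserWarning, match="percent change undefined"):
        out = ev.compare_hit_miss(x, np.array([-1.0, 0.0, 1.0]))
    assert np.isnan(out["percent_change"])
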