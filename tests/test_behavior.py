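import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import erfinv

from vmtask import behavior
from vmtask.behavior import (
    LickEventTrain,
    build_trial_table,
    classify_performance,
    compute_d_prime,
    detect_licks,
    reaction_times,
)
from vmtask.session_io import ValidationError
from vmtask.synthetic_data import SimulationConfig, _draw_reaction_time


def _phi_inv(p):
    # independent normal-quantile oracle (erfinv-based)
    return np.sqrt(2.0) * erfinv(2.0 * p - 1.0)


# ---------------------------------------------------------------------------
# lick detection

def test_flat_trace_has_no_licks():
    assert len(detect_licks(np.zeros(10000), 1000.0)) == 0


def test_single_pulse_contact_time_is_pulse_onset():
    rate = 1000.0
    trace = np.zeros(10000)
    trace[5000:5100] = 1.0
    train = detect_licks(trace, rate, threshold=0.5)
    np.testing.assert_allclose(train.contact_times, [5.0])


def test_pulses_closer_than_debounce_merge():
    rate = 1000.0
    trace = np.zeros(8000)
    trace[5000:5010] = 1.0
    trace[5030:5040] = 1.0  # 30 ms later
    train = detect_licks(trace, rate, threshold=0.5, debounce_s=0.05)
    np.testing.assert_allclose(train.contact_times, [5.0])
    # beyond the debounce the second pulse is its own contact
    trace2 = np.zeros(8000)
    trace2[5000:5010] = 1.0
    trace2[5070:5080] = 1.0
    train2 = detect_licks(trace2, rate, threshold=0.5, debounce_s=0.05)
    np.testing.assert_allclose(train2.contact_times, [5.0, 5.07])


def test_non_finite_trace_rejected():
    trace = np.zeros(100)
    trace[3] = np.nan
    with pytest.raises(ValidationError):
        detect_licks(trace, 1000.0)


# ---------------------------------------------------------------------------
# trial table

def test_hit_miss_and_window_boundary():
    licks = LickEventTrain(np.array([10.3]))
    trials = build_trial_table([10.0, 20.0], [], licks)
    assert list(trials["outcome"]) == ["hit", "miss"]
    assert trials.loc[0, "reaction_time"] == pytest.approx(0.3)
    # the reward window is half-open: a lick exactly 1 s after the
    # stimulus does not count
    late = build_trial_table([10.0], [], LickEventTrain(np.array([11.0])))
    assert list(late["outcome"]) == ["miss"]


def test_catch_trial_outcomes():
    licks = LickEventTrain(np.array([31.2]))  # 1.2 s after the catch time
    trials = build_trial_table([], [30.0], licks)
    assert list(trials["outcome"]) == ["correct_rejection"]
    fa = build_trial_table([], [30.0], LickEventTrain(np.array([30.4])))
    assert list(fa["outcome"]) == ["false_alarm"]
    assert fa.loc[0, "reaction_time"] == pytest.approx(0.4)


def test_overlapping_trial_windows_rejected():
    with pytest.raises(ValidationError, match="overlap"):
        build_trial_table([10.0], [10.5], LickEventTrain(np.empty(0)))


def test_abort_rule_violation_is_flagged():
    licks = LickEventTrain(np.array([9.5]))
    with pytest.warns(UserWarning, match="abort"):
        build_trial_table([10.0], [], licks)


@settings(max_examples=60, deadline=None)
@given(st.data())
def test_outcomes_partition_trials_and_match_bruteforce(data):
    """hits+misses = n_test and FA+CR = n_catch on random event streams,
    trial-by-trial identical to a brute-force classification loop."""
    n_trials = data.draw(st.integers(1, 12))
    gaps = data.draw(st.lists(
        st.floats(1.0, 9.0, allow_nan=False), min_size=n_trials,
        max_size=n_trials))
    times = 2.0 + np.cumsum(np.asarray(gaps) + 1.0)
    kinds = data.draw(st.lists(st.booleans(), min_size=n_trials,
                               max_size=n_trials))
    stim = times[np.asarray(kinds)]
    catch = times[~np.asarray(kinds)]
    n_licks = data.draw(st.integers(0, 15))
    licks = np.sort(data.draw(st.lists(
        st.floats(0.0, float(times[-1]) + 2.0, allow_nan=False),
        min_size=n_licks, max_size=n_licks, unique=True)))
    # avoid zero-reaction-time coincidences
    if np.intersect1d(licks, times).size:
        licks = licks + 1e-6
    trials = build_trial_table(stim, catch, LickEventTrain(licks))

    test_rows = trials[trials["type"] == "test"]
    catch_rows = trials[trials["type"] == "catch"]
    assert (test_rows["outcome"].isin(["hit", "miss"])).all()
    assert (catch_rows["outcome"].isin(
        ["false_alarm", "correct_rejection"])).all()
    assert len(test_rows) == len(stim)
    assert len(catch_rows) == len(catch)
    for row in trials.itertuples():
        in_window = [t for t in licks
                     if row.stim_time <= t < row.stim_time + 1.0]
        responded = bool(in_window)
        expected = ("hit" if responded else "miss") \
            if row.type == "test" else \
            ("false_alarm" if responded else "correct_rejection")
        assert row.outcome == expected
        if responded:
            assert row.first_lick_time == in_window[0]


# ---------------------------------------------------------------------------
# d-prime

def test_d_prime_zero_when_rates_equal():
    assert compute_d_prime(5, 10, 5, 10) == pytest.approx(0.0, abs=1e-12)


def test_d_prime_matches_quantile_oracle():
    got = compute_d_prime(77, 100, 17, 100)
    want = _phi_inv(0.77) - _phi_inv(0.17)
    assert got == pytest.approx(want, abs=1e-9)
    assert got == pytest.approx(1.693, abs=5e-3)


def test_zero_rate_corrected_by_half_trial_count():
    got = compute_d_prime(8, 10, 0, 10)
    want = _phi_inv(0.8) - _phi_inv(0.05)  # FAR 0 -> 1/(2*10)
    assert got == pytest.approx(want, abs=1e-9)


@given(hits=st.integers(0, 25), fas=st.integers(0, 25),
       n_test=st.integers(1, 25), n_catch=st.integers(1, 25))
@settings(max_examples=200, deadline=None)
def test_d_prime_finite_and_antisymmetric(hits, fas, n_test, n_catch):
    hits = min(hits, n_test)
    fas = min(fas, n_catch)
    d = compute_d_prime(hits, n_test, fas, n_catch)
    assert np.isfinite(d)
    # swapping the roles of the two rates negates d'
    d_swapped = compute_d_prime(fas, n_catch, hits, n_test)
    assert d == pytest.approx(-d_swapped, abs=1e-12)


def test_d_prime_monotone_in_both_rates():
    base = compute_d_prime(10, 20, 5, 20)
    assert compute_d_prime(11, 20, 5, 20) > base
    assert compute_d_prime(10, 20, 6, 20) < base


def test_zero_trials_is_an_error():
    with pytest.raises(ValueError):
        compute_d_prime(0, 0, 0, 10)


# ---------------------------------------------------------------------------
# gating and reaction times

@pytest.mark.parametrize("d, label", [
    (2.12, "good_performer"),
    (1.0, "indeterminate"),
    (0.03, "naive"),
    (1.1, "indeterminate"),
    (0.9, "indeterminate"),
])
def test_performance_gates(d, label):
    assert classify_performance(d) == label


def test_reaction_time_summaries():
    import pandas as pd
    from vmtask.session_io import TRIAL_COLUMNS
    rows = [(0, "test", 10.0, "hit", 10.317, 0.317)]
    one = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    assert reaction_times(one)["mean"] == pytest.approx(0.317)
    rows = [(0, "test", 10.0, "hit", 10.2, 0.2),
            (1, "test", 20.0, "hit", 20.4, 0.4)]
    two = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    assert reaction_times(two)["mean"] == pytest.approx(0.3)
    empty = pd.DataFrame([(0, "test", 10.0, "miss", np.nan, np.nan)],
                         columns=TRIAL_COLUMNS)
    with pytest.warns(UserWarning, match="no hit"):
        out = reaction_times(empty)
    assert out["n"] == 0


def test_simulated_latency_distribution_recovers_mean():
    """200 draws from the trained-mouse latency model average to the
    configured 317 ms within 3 standard errors."""
    cfg = SimulationConfig()
    rng = np.random.default_rng(99)
    draws = np.array([_draw_reaction_time(cfg, rng) for _ in range(200)])
    assert np.all((draws > 0.05) & (draws < 1.0))
    sem = draws.std(ddof=1) / np.sqrt(draws.size)
    assert abs(draws.mean() - 0.317) < 3 * sem + 0.01
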