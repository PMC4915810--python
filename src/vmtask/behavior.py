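"""Lick detection, trial parsing and signal-detection performance.

The detection task: on *test* trials a brief whisker deflection is
delivered and the mouse earns a water reward by licking within a 1-s
window; *catch* trials have no stimulus and measure spontaneous licking.
Performance is summarized by the discriminability index
``d' = Phi^-1(HR) - Phi^-1(FAR)`` where HR and FAR are the hit and
false-alarm rates and Phi^-1 is the standard normal quantile. Rates
measured as exactly 0 or 1 are corrected by 1/(2N) (N the trial count of
the rate being corrected) so d' stays finite. Recordings are gated into
'good performer' (d' > 1.1) or 'naive' (d' < 0.9) groups; anything in
between is indeterminate and excluded downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .session_io import TRIAL_COLUMNS, ValidationError, validate_trial_table

GOOD_PERFORMER_DPRIME = 1.1
NAIVE_DPRIME = 0.9


@dataclass
class LickEventTrain:
    """Times (s) when the tongue first contacts the spout, per lick."""

    contact_times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.contact_times, dtype=float).ravel()
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValidationError("contact_times must be strictly increasing")
        self.contact_times = t

    def __len__(self):
        return len(self.contact_times)


@dataclass
class PerformanceSummary:
    n_test: int
    n_catch: int
    hit_rate: float
    false_alarm_rate: float
    d_prime: float
    mean_reaction_time: float
    group_label: str


def detect_licks(
    lick_trace,
    sample_rate: float,
    threshold: float | None = None,
    debounce_s: float = 0.05,
) -> LickEventTrain:
    """Detect individual tongue-spout contacts from the sensor trace.

    A contact is the first sample of a supra-threshold excursion whose
    onset is at least ``debounce_s`` after the end of the previous
    excursion; closer excursions are merged (sensor bounce).

    ``threshold`` defaults to the midpoint between the 5th and 95th
    percentile of the trace (falling back to the min/max midpoint when
    those coincide); a flat trace yields no licks.
    """
    x = np.asarray(lick_trace, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValidationError("lick trace contains non-finite samples")
    if x.size == 0:
        return LickEventTrain(np.empty(0))
    if threshold is None:
        lo, hi = np.percentile(x, [5, 95])
        if hi <= lo:
            lo, hi = x.min(), x.max()
        threshold = 0.5 * (lo + hi)
    above = x > threshold
    if not above.any():
        return LickEventTrain(np.empty(0))
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(x)]
    keep = []
    last_end = None
    min_gap = debounce_s * sample_rate
    for s, e in zip(starts, ends):
        if last_end is not None and (s - last_end) < min_gap:
            last_end = e  # merged into the previous excursion
            continue
        keep.append(s)
        last_end = e
    return LickEventTrain(np.asarray(keep, dtype=float) / sample_rate)


def build_trial_table(
    stim_times,
    catch_times,
    licks: LickEventTrain,
    reward_window_s: float = 1.0,
    abort_lookback_s: float = 2.0,
) -> pd.DataFrame:
    """Classify every delivered trial from the event streams.

    A test trial is a *hit* iff a lick falls in ``[stim, stim + window)``
    (else *miss*); a catch trial is a *false alarm* iff a lick falls in the
    same window after its virtual stimulus time (else *correct rejection*).
    The scheduler should have aborted any trial preceded by licking within
    ``abort_lookback_s``; delivered trials violating that rule are counted
    and reported with a warning, not dropped.
    """
    stim = np.asarray(stim_times, dtype=float)
    catch = np.asarray(catch_times, dtype=float)
    lick = np.asarray(licks.contact_times, dtype=float)
    times = np.concatenate([stim, catch])
    kinds = np.array(["test"] * len(stim) + ["catch"] * len(catch))
    order = np.argsort(times, kind="stable")
    times, kinds = times[order], kinds[order]
    if len(times) > 1 and np.any(np.diff(times) < reward_window_s):
        raise ValidationError("trial reward windows overlap")

    rows = []
    n_violations = 0
    for i, (t, kind) in enumerate(zip(times, kinds)):
        j = np.searchsorted(lick, t, side="left")
        responded = j < len(lick) and lick[j] < t + reward_window_s
        first_lick = lick[j] if responded else np.nan
        rt = first_lick - t if responded else np.nan
        if kind == "test":
            outcome = "hit" if responded else "miss"
        else:
            outcome = "false_alarm" if responded else "correct_rejection"
        k = np.searchsorted(lick, t - abort_lookback_s, side="left")
        if k < j:  # a lick in [t - lookback, t)
            n_violations += 1
        rows.append((i, kind, t, outcome, first_lick, rt))
    if n_violations:
        warnings.warn(
            f"{n_violations} delivered trial(s) have licks within the "
            f"{abort_lookback_s:g} s abort lookback; scheduler rule violated",
            stacklevel=2,
        )
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return validate_trial_table(trials)


def compute_d_prime(hits: int, n_test: int, fas: int, n_catch: int) -> float:
    """d' from raw counts with the 1/(2N) endpoint correction.

    A rate measured as exactly 0 is replaced by ``1/(2N)`` and a rate of
    exactly 1 by ``1 - 1/(2N)``, with N the trial count of that rate, so
    the normal quantiles stay finite.
    """
    if n_test < 1 or n_catch < 1:
        raise ValueError("need at least one test and one catch trial")
    if not (0 <= hits <= n_test and 0 <= fas <= n_catch):
        raise ValueError("counts exceed trial numbers")
    hr = hits / n_test
    far = fas / n_catch
    if hr == 0.0:
        hr = 1.0 / (2 * n_test)
    elif hr == 1.0:
        hr = 1.0 - 1.0 / (2 * n_test)
    if far == 0.0:
        far = 1.0 / (2 * n_catch)
    elif far == 1.0:
        far = 1.0 - 1.0 / (2 * n_catch)
    return float(stats.norm.ppf(hr) - stats.norm.ppf(far))


def classify_performance(
    d_prime: float,
    good_threshold: float = GOOD_PERFORMER_DPRIME,
    naive_threshold: float = NAIVE_DPRIME,
) -> str:
    """Gate a recording by its d': good_performer / naive / indeterminate."""
    if d_prime > good_threshold:
        return "good_performer"
    if d_prime < naive_threshold:
        return "naive"
    return "indeterminate"


def reaction_times(trials: pd.DataFrame) -> dict:
    """Per-hit reaction times with mean +/- sem.

    Reaction time is first lick minus stimulus onset, hit trials only.
    Returns ``{'values', 'mean', 'sem', 'n'}``; with no hits the result is
    empty (``n == 0``, NaN summaries) and a warning is issued.
    """
    rt = trials.loc[trials["outcome"] == "hit", "reaction_time"].to_numpy()
    if rt.size == 0:
        warnings.warn("no hit trials: reaction-time summary is empty",
                      stacklevel=2)
        return {"values": rt, "mean": np.nan, "sem": np.nan, "n": 0}
    sem = float(np.std(rt, ddof=1) / np.sqrt(rt.size)) if rt.size > 1 else np.nan
    return {"values": rt, "mean": float(np.mean(rt)), "sem": sem,
            "n": int(rt.size)}


def summarize_performance(trials: pd.DataFrame) -> PerformanceSummary:
    """Counts, raw rates, corrected d', mean RT and the group gate."""
    test = trials[trials["type"] == "test"]
    catch = trials[trials["type"] == "catch"]
    n_test, n_catch = len(test), len(catch)
    hits = int((test["outcome"] == "hit").sum())
    fas = int((catch["outcome"] == "false_alarm").sum())
    d = compute_d_prime(hits, n_test, fas, n_catch)
    rt = reaction_times(trials) if hits else {"mean": np.nan}
    return PerformanceSummary(
        n_test=n_test,
        n_catch=n_catch,
        hit_rate=hits / n_test,
        false_alarm_rate=fas / n_catch,
        d_prime=d,
        mean_reaction_time=rt["mean"],
        group_label=classify_performance(d),
    )
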