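"""Session data model and container I/O.

A *session* is one whole-cell recording during the detection task: a
membrane-potential (Vm) trace, a lick-sensor trace, the delivered stimulus
and water-valve event times, and recording metadata. Sessions are stored in
a self-describing HDF5 layout::

    /traces/vm              float array, mV        attrs: sample_rate_hz
    /traces/lick            float array, a.u.      attrs: sample_rate_hz
    /events/stimulus_times  float array, s (test trials, whisker deflection)
    /events/catch_times     float array, s (virtual stimulus of catch trials)
    /events/valve_times     float array, s (water valve openings)
    /meta                   group, attrs: mouse_id, cell_id,
                            projection_target, group, liquid_junction_corrected

All times are seconds from recording start; all analysis windows elsewhere
in the package are half-open ``[t0, t1)``; Vm is in mV. An alternative
sweep-wise layout (``/sweeps/NNNN/...`` with a ``start_time_s`` attribute
per sweep) is concatenated transparently on read, mapping sweep-local event
times into session time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

PROJECTION_TARGETS = ("M1-p", "S2-p")
GROUPS = ("good_performer", "naive")

#: Column order of the trial-table CSV export.
TRIAL_COLUMNS = [
    "trial_id",
    "type",
    "stim_time",
    "outcome",
    "first_lick_time",
    "reaction_time",
]

TRIAL_TYPES = ("test", "catch")
OUTCOMES = ("hit", "miss", "false_alarm", "correct_rejection")


class FormatError(Exception):
    """A container file does not conform to the documented layout."""


class ValidationError(ValueError):
    """Data violate a session or trial-table invariant."""


def _as_sorted_events(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size and not np.all(np.isfinite(x)):
        raise ValidationError(f"{name} contains non-finite values")
    if x.size > 1 and np.any(np.diff(x) <= 0):
        raise ValidationError(f"{name} must be strictly increasing")
    return x


@dataclass
class SessionRecording:
    """Raw traces, event times and metadata for one whole-cell recording.

    Parameters
    ----------
    vm_trace : array
        Membrane potential in mV, sampled at ``sample_rate_vm``.
    lick_trace : array
        Lick-sensor signal (arbitrary units) at ``sample_rate_lick``; may be
        a different rate from the Vm trace.
    stim_times, catch_times, valve_times : array
        Event times in seconds from recording start, strictly increasing.
        ``catch_times`` are the virtual stimulus times of delivered catch
        trials (no whisker deflection occurs).
    meta : dict
        ``mouse_id``, ``cell_id``, ``projection_target`` ('M1-p'/'S2-p'),
        ``group`` ('good_performer'/'naive'),
        ``liquid_junction_corrected`` (bool; recordings are conventionally
        left uncorrected).
    """

    vm_trace: np.ndarray
    lick_trace: np.ndarray
    sample_rate_vm: float = 20000.0
    sample_rate_lick: float = 20000.0
    stim_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    catch_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    valve_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vm_trace = np.asarray(self.vm_trace, dtype=float).ravel()
        self.lick_trace = np.asarray(self.lick_trace, dtype=float).ravel()
        if self.sample_rate_vm <= 0 or self.sample_rate_lick <= 0:
            raise ValidationError("sample rates must be positive")
        if not np.all(np.isfinite(self.vm_trace)):
            raise ValidationError("vm_trace contains non-finite values")
        self.stim_times = _as_sorted_events(self.stim_times, "stim_times")
        self.catch_times = _as_sorted_events(self.catch_times, "catch_times")
        self.valve_times = _as_sorted_events(self.valve_times, "valve_times")
        dur = self.duration_s
        for name in ("stim_times", "catch_times", "valve_times"):
            ev = getattr(self, name)
            if ev.size and (ev[0] < 0 or ev[-1] > dur):
                raise ValidationError(
                    f"{name} outside recording [0, {dur:.3f}] s"
                )
        tgt = self.meta.get("projection_target")
        if tgt is not None and tgt not in PROJECTION_TARGETS:
            raise ValidationError(f"unknown projection_target {tgt!r}")
        grp = self.meta.get("group")
        if grp is not None and grp not in GROUPS:
            raise ValidationError(f"unknown group {grp!r}")

    @property
    def duration_s(self) -> float:
        return len(self.vm_trace) / self.sample_rate_vm


def write_session(session: SessionRecording, path) -> str:
    """Write a session to the hierarchical container; returns ``path``.

    Arrays round-trip bit-identically (stored at native float64).
    """
    with h5py.File(path, "w") as f:
        tr = f.create_group("traces")
        d = tr.create_dataset("vm", data=session.vm_trace)
        d.attrs["sample_rate_hz"] = float(session.sample_rate_vm)
        d.attrs["units"] = "mV"
        d = tr.create_dataset("lick", data=session.lick_trace)
        d.attrs["sample_rate_hz"] = float(session.sample_rate_lick)
        ev = f.create_group("events")
        ev.create_dataset("stimulus_times", data=session.stim_times)
        ev.create_dataset("catch_times", data=session.catch_times)
        ev.create_dataset("valve_times", data=session.valve_times)
        mg = f.create_group("meta")
        for k, v in session.meta.items():
            mg.attrs[k] = v
    return str(path)


def _require(f, key):
    if key not in f:
        raise FormatError(f"container is missing required dataset {key!r}")
    return f[key]


def read_session(path) -> SessionRecording:
    """Read a session container (continuous or sweep-wise layout)."""
    with h5py.File(path, "r") as f:
        if "sweeps" in f:
            return _read_sweeps(f)
        vm = _require(f, "/traces/vm")
        lick = _require(f, "/traces/lick")
        rate_vm = float(vm.attrs.get("sample_rate_hz", 20000.0))
        rate_lick = float(lick.attrs.get("sample_rate_hz", rate_vm))
        stim = _require(f, "/events/stimulus_times")[()]
        catch = f["/events/catch_times"][()] if "/events/catch_times" in f \
            else np.empty(0)
        valve = _require(f, "/events/valve_times")[()]
        meta = dict(f["meta"].attrs) if "meta" in f else {}
        meta = {k: (v.item() if hasattr(v, "item") else v)
                for k, v in meta.items()}
        return SessionRecording(
            vm_trace=vm[()],
            lick_trace=lick[()],
            sample_rate_vm=rate_vm,
            sample_rate_lick=rate_lick,
            stim_times=stim,
            catch_times=catch,
            valve_times=valve,
            meta=meta,
        )


def _read_sweeps(f) -> SessionRecording:
    """Concatenate short acquisition sweeps into one continuous session.

    Each ``/sweeps/NNNN`` group mirrors the continuous layout with
    sweep-local event times and carries ``start_time_s``; events are shifted
    into session time. Sweeps are assumed contiguous (acquisition gaps are
    not modeled).
    """
    names = sorted(f["sweeps"].keys())
    if not names:
        raise FormatError("container has an empty /sweeps group")
    vm_parts, lick_parts = [], []
    stim, catch, valve = [], [], []
    rate_vm = rate_lick = None
    for name in names:
        g = f["sweeps"][name]
        vm = _require(g, "traces/vm")
        t0 = float(g.attrs.get("start_time_s", 0.0))
        rate_vm = float(vm.attrs.get("sample_rate_hz", 20000.0))
        vm_parts.append(vm[()])
        lick = _require(g, "traces/lick")
        rate_lick = float(lick.attrs.get("sample_rate_hz", rate_vm))
        lick_parts.append(lick[()])
        for src, dst in (("stimulus_times", stim), ("catch_times", catch),
                         ("valve_times", valve)):
            if f"events/{src}" in g:
                dst.extend(np.asarray(g[f"events/{src}"][()]) + t0)
    meta = dict(f["meta"].attrs) if "meta" in f else {}
    meta = {k: (v.item() if hasattr(v, "item") else v) for k, v in meta.items()}
    return SessionRecording(
        vm_trace=np.concatenate(vm_parts),
        lick_trace=np.concatenate(lick_parts),
        sample_rate_vm=rate_vm,
        sample_rate_lick=rate_lick,
        stim_times=np.sort(stim),
        catch_times=np.sort(catch),
        valve_times=np.sort(valve),
        meta=meta,
    )


def validate_trial_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Check trial-table invariants; returns the table unchanged."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValidationError(f"trial table missing columns {missing}")
    bad_type = ~trials["type"].isin(TRIAL_TYPES)
    if bad_type.any():
        raise ValidationError("trial table has unknown trial types")
    test = trials["type"] == "test"
    if not trials.loc[test, "outcome"].isin(("hit", "miss")).all():
        raise ValidationError("test trials must be hit or miss")
    if not trials.loc[~test, "outcome"].isin(
            ("false_alarm", "correct_rejection")).all():
        raise ValidationError("catch trials must be FA or CR")
    resp = trials["outcome"].isin(("hit", "false_alarm"))
    rt = trials.loc[resp, "reaction_time"]
    if rt.isna().any() or (rt <= 0).any():
        raise ValidationError("hit/FA trials need a positive reaction time")
    return trials


def export_trial_table(trials: pd.DataFrame, path) -> str:
    """Write a trial table as CSV (documented column order); lossless."""
    validate_trial_table(trials)
    trials.loc[:, TRIAL_COLUMNS].to_csv(path, index=False)
    return str(path)


def read_trial_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"trial_id": int, "type": str, "outcome": str},
    )
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trial-table file missing columns {missing}")
    return validate_trial_table(df[TRIAL_COLUMNS])
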