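"""Analysis configuration: defaults plus YAML overrides.

The config file is a flat two-level YAML mapping whose sections mirror the
pipeline stages::

    behavior:
      lick_threshold: null        # null -> percentile midpoint
      lick_debounce_s: 0.05
      reward_window_s: 1.0
      abort_lookback_s: 2.0
    preprocess:
      dvdt_threshold: 10.0        # mV/ms
      peak_threshold: null        # null -> median Vm + 25 mV
      refractory_s: 0.002
      median_window_s: 0.008
    evoked:
      align_window: [-1.0, 2.0]
      psth_bin_s: 0.05
    licks:
      bout_gap_s: 1.0
      min_after_stim_s: 3.0
      min_after_bout_s: 1.0

Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import copy

import yaml

DEFAULT_CONFIG: dict = {
    "behavior": {
        "lick_threshold": None,
        "lick_debounce_s": 0.05,
        "reward_window_s": 1.0,
        "abort_lookback_s": 2.0,
    },
    "preprocess": {
        "dvdt_threshold": 10.0,
        "peak_threshold": None,
        "refractory_s": 0.002,
        "median_window_s": 0.008,
    },
    "evoked": {
        "align_window": (-1.0, 2.0),
        "psth_bin_s": 0.05,
    },
    "licks": {
        "bout_gap_s": 1.0,
        "min_after_stim_s": 3.0,
        "min_after_bout_s": 1.0,
    },
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def load_config(path=None) -> dict:
    """Defaults merged with a YAML override file (section by section)."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as f:
        user = yaml.safe_load(f) or {}
    for section, values in user.items():
        if section not in cfg:
            raise KeyError(f"unknown config section {section!r}")
        if values is None:
            continue
        for key, val in values.items():
            if key not in cfg[section]:
                raise KeyError(f"unknown config key {section}.{key!r}")
            cfg[section][key] = tuple(val) if isinstance(val, list) else val
    return cfg
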