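"""Glue between simulated (or sorted) trials and the statistics layer.

Builds tidy per-trial response tables (peak rate, transient-window mean
rate, onset latency) from a :class:`~sensillab.sensillum.TrialTable`, and
runs the complete onset-asynchrony analysis — normalization to the cognate
response, FDR-corrected test battery, synchrony-window width and pooled
regression — in one call.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import (
    KernelParams,
    estimate_rate,
    response_onset_latency,
    response_peak_rate,
    window_mean_rate,
)
from .sensillum import SpikeTrain, TrialTable
from .sorting import SortOptions, bandpass_and_detect, sort_two_units
from .stats import (
    asynchrony_test_battery,
    normalize_to_cognate,
    pooled_synchrony_regression,
    synchrony_window_width,
)


def response_table(
    trials: TrialTable,
    metrics: tuple[str, ...] = ("peak_rate",),
    kernel: KernelParams = KernelParams(),
    peak_window: tuple[float, float] = (0.0, 0.5),
    transient_window: tuple[float, float] = (0.1, 0.35),
    baseline_window: tuple[float, float] = (-0.4, 0.0),
) -> pd.DataFrame:
    """One row per (trial, unit, metric).

    ``peak_rate`` is the maximum alpha-kernel rate estimate in
    ``peak_window`` shifted to start at the unit's own cognate-odorant
    valve opening (so leading and trailing units get equally long search
    windows); ``window_mean_rate`` the spike count rate in
    ``transient_window``; ``onset_latency`` the first sustained threshold
    crossing after t = 0.
    """
    rows = []
    for tr in trials:
        proto = tr.protocol
        for unit, train in tr.trains.items():
            own = proto.channels[unit]
            own_onset = (
                float(own.toggle_times[0]) - proto.time_origin
                if own.toggle_times.size
                else 0.0
            )
            for metric in metrics:
                if metric == "window_mean_rate":
                    value = window_mean_rate(train, transient_window)
                else:
                    win = (peak_window[0] + own_onset, peak_window[1] + own_onset)
                    rate = estimate_rate(
                        train,
                        kernel,
                        t_start=baseline_window[0],
                        t_stop=max(win[1], 0.5) + 0.2,
                    )
                    if metric == "peak_rate":
                        value = response_peak_rate(rate, win)
                    elif metric == "onset_latency":
                        value = response_onset_latency(rate, baseline_window)
                        value = np.nan if value is None else value
                    else:
                        raise ValueError(f"unknown metric {metric!r}")
                rows.append(
                    {
                        "fly_id": tr.fly_id,
                        "stimulus_id": tr.stimulus_id,
                        "onset_asynchrony_ms": proto.onset_asynchrony_ms,
                        "mixture_mode": proto.mixture_mode,
                        "level": proto.level,
                        "trial": tr.trial_index,
                        "unit": unit,
                        "metric": metric,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)


def asynchrony_analysis(
    trials: TrialTable,
    unit: str = "B",
    kernel: KernelParams = KernelParams(),
    alpha: float = 0.05,
) -> dict:
    """Full onset-asynchrony analysis for one unit.

    Returns the normalized response table, the FDR-corrected battery, the
    synchrony-window summary and the pooled synchrony regression.
    """
    table = response_table(trials, metrics=("peak_rate",), kernel=kernel)
    table = table[table["metric"] == "peak_rate"]
    normalized = normalize_to_cognate(table)
    battery = asynchrony_test_battery(normalized, unit=unit, alpha=alpha)
    window = synchrony_window_width(battery, alpha=alpha)
    regression = pooled_synchrony_regression(normalized, unit=unit)
    return {
        "normalized": normalized,
        "battery": battery,
        "window": window,
        "regression": regression,
    }


def sort_trial_table(trials: TrialTable, options: SortOptions = SortOptions()) -> TrialTable:
    """Replace ground-truth trains with trains recovered by spike sorting.

    Events are detected per trial trace, pooled per fly (rate estimation
    stays within trials) and sorted with the amplitude-vs-rate model; the
    resulting labels are split back into per-trial spike trains.  Trials
    must carry synthesized voltage traces.
    """
    by_fly: dict[int, list] = {}
    index: dict[int, list] = {}
    for pos, tr in enumerate(trials):
        if tr.trace is None:
            raise ValueError("trial has no voltage trace; simulate with synthesize=True")
        events = bandpass_and_detect(tr.trace, trial_id=pos)
        by_fly.setdefault(tr.fly_id, []).extend(events)
        index.setdefault(tr.fly_id, []).append(pos)
    out = TrialTable(protocols=dict(trials.protocols))
    sorted_trains: dict[int, dict[str, np.ndarray]] = {}
    for fly, events in by_fly.items():
        result = sort_two_units(events, options)
        for ev, label in zip(result.events, result.labels):
            pos = ev.trial_id
            sorted_trains.setdefault(pos, {"A": [], "B": []})
            if label in ("A", "B"):
                sorted_trains[pos][label].append(ev.time)
    from dataclasses import replace

    for pos, tr in enumerate(trials):
        per_unit = sorted_trains.get(pos, {"A": [], "B": []})
        trains = {
            unit: SpikeTrain(
                np.sort(np.asarray(per_unit[unit], dtype=float)),
                unit=unit,
                fly_id=tr.fly_id,
                stimulus_id=tr.stimulus_id,
                trial_index=tr.trial_index,
            )
            for unit in ("A", "B")
        }
        out.trials.append(replace(tr, trains=trains))
    return out
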