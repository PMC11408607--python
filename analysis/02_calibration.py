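#!/usr/bin/env python
"""Calibrate the simulated ORNs against the published firing-rate bands.

Simulates uncoupled cognate responses at both concentration levels and
reports the transient peak (alpha-kernel estimate) and the sustained rate
2 s into a constant stimulus.  Targets: low concentration ~70-75 spikes/s
peak and ~21-25 spikes/s sustained; high ~120-230 and ~35-52 spikes/s.

Writes: results/calibration.json.
"""

import json
from pathlib import Path

import numpy as np

from sensillab.metrics import KernelParams, estimate_rate, response_peak_rate, window_mean_rate
from sensillab.sensillum import SensillumParams, simulate_trial
from sensillab.stimuli import StimulusProtocol, ValveSequence, _closed, make_pulse_protocol

N_TRIALS = 100
s = SensillumParams(fly_jitter_cv=0.0, trial_jitter_cv=0.0, g_ab=0.0, g_ba=0.0)

out = {}
for level in ("low", "high"):
    pulse = make_pulse_protocol("A", 0.5, level)
    const = StimulusProtocol(
        channels={"A": ValveSequence(np.array([0.0]), 3.0, "A"), "B": _closed("B", 3.0)},
        kind="pulse", level=level, label="A",
    )
    peaks, sustained = [], []
    for i in range(N_TRIALS):
        tr = simulate_trial(pulse, s, seed=np.random.SeedSequence((1, i)))
        rate = estimate_rate(tr.trains["A"], KernelParams(0.05), t_start=-0.4, t_stop=1.0)
        peaks.append(response_peak_rate(rate, (0.0, 0.5)))
        tr = simulate_trial(const, s, seed=np.random.SeedSequence((2, i)), pad_post=0.0)
        sustained.append(window_mean_rate(tr.trains["A"], (2.0, 2.5)))
    out[level] = {
        "peak_mean": float(np.mean(peaks)),
        "peak_sd": float(np.std(peaks)),
        "sustained_mean": float(np.mean(sustained)),
        "sustained_sd": float(np.std(sustained)),
    }
    print(f"{level}: transient peak {out[level]['peak_mean']:.1f} spikes/s, "
          f"sustained at 2 s {out[level]['sustained_mean']:.1f} spikes/s")

Path("results").mkdir(exist_ok=True)
with open("results/calibration.json", "w") as fh:
    json.dump(out, fh, indent=1)
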