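#!/usr/bin/env python
"""Build and inspect the stimulus designs.

Verifies the olfactometer dilution arithmetic against the published flow
settings, generates the pseudorandom fluctuating valve sequences, and
exports example protocols and a concentration trace.

Writes: results/stimuli/{dilution.json, protocol_*.json, pid_example.csv}.
"""

import json
from pathlib import Path

import numpy as np

from sensillab.stimuli import (
    FlowConfig,
    compute_air_dilution,
    generate_poisson_valve_sequence,
    make_asynchrony_stimulus_grid,
    make_background_pulse_protocol,
    make_fluctuating_mixture_set,
    valve_to_concentration,
)

OUT = Path("results/stimuli")
OUT.mkdir(parents=True, exist_ok=True)

dilution = compute_air_dilution(FlowConfig())
with open(OUT / "dilution.json", "w") as fh:
    json.dump(dilution, fh, indent=1)
print(f"high-concentration dilution {dilution['dilution_fraction']:.3g} "
      f"at total outlet flow {dilution['total_flow']:.2f} L/min")

seq = generate_poisson_valve_sequence(10.0, 0.05, seed=1)
print(f"pseudorandom sequence: {len(seq.toggle_times)} toggles in 10 s "
      f"(mean interval {np.diff(seq.toggle_times).mean()*1000:.1f} ms), "
      f"valve open {seq.open_time():.1f} s")

grid = make_asynchrony_stimulus_grid("low")
print(f"onset-asynchrony design: {len(grid)} stimuli -> {sorted(grid)}")
grid["A96B"].to_json(OUT / "protocol_A96B.json")
make_background_pulse_protocol("B", "A").to_json(OUT / "protocol_A_on_B.json")

fluct = make_fluctuating_mixture_set(level="high")
fluct["AB_i"].to_json(OUT / "protocol_ABi.json")
conc = valve_to_concentration(fluct["AB_i"].channels["A"], peak_conc=1.43e-3,
                              tau_rise=0.010, tau_fall=0.015)
conc.to_csv(OUT / "pid_example.csv")
print(f"wrote example protocols and a PID-style concentration trace to {OUT}/")
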