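"""End-to-end orchestration of the figure-style reproduction experiments.

Each run simulates a whole multi-fly experiment from its preset design,
optionally replaces ground-truth spike trains by sorted ones, computes the
response metrics, runs the statistics, and writes tidy CSV/JSON artifacts
plus a manifest (config snapshot, stage timings, output hashes) to the run
directory.  Identical config + seed give identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    PRESET_FLIES_PER_LEVEL,
    PRESETS,
    RunConfig,
    RunManifest,
    StageTimer,
    write_spike_csv,
)
from .metrics import KernelParams
from .pipeline import asynchrony_analysis, response_table, sort_trial_table
from .sensillum import SensillumParams, TrialTable, simulate_experiment
from .stats import (
    DEFAULT_DVP_PAIRS,
    dvp_comparison_groups,
    paired_t_test,
    utest_bonferroni,
)
from .stimuli import (
    StimulusProtocol,
    make_asynchrony_stimulus_grid,
    make_background_pulse_protocol,
    make_fluctuating_mixture_set,
    make_pulse_protocol,
)

#: U-test comparisons quantifying the correlated-vs-uncorrelated mixture
#: effect and its controls, per recorded unit (each unit is compared on the
#: stimulus pairs involving its own cognate odorant).
DVP_COMPARISONS = {
    "A": [("(AB_i, A)", "(A, A)"), ("(AB_A, A)", "(AB_i, A)")],
    "B": [("(AB_i, B)", "(B, B)"), ("(AB_B, B)", "(AB_i, B)")],
}


def build_protocols(experiment: str, level: str, seed: int = 0) -> dict[str, StimulusProtocol]:
    """Stimulus set of one experiment design at one concentration level."""
    if experiment == "fig2":
        protos = {}
        for ch in ("A", "B"):
            p = make_pulse_protocol(ch, 0.5, level)
            protos[p.label] = p
        for bg, pulse in (("B", "A"), ("A", "B")):
            p = make_background_pulse_protocol(bg, pulse, 2.0, 0.5, level)
            protos[p.label] = p
        return protos
    if experiment == "fig3":
        return make_asynchrony_stimulus_grid(level)
    if experiment == "fig4":
        # one fixed pseudorandom sequence pair serves as the stimulus for the
        # whole experiment (the valve sequences are part of the study design,
        # not of the biological randomness the seed controls)
        return make_fluctuating_mixture_set(level=level)
    raise ValueError(f"no stimulus builder for experiment {experiment!r}")


def simulate_preset(
    config: RunConfig, level: str, synthesize: bool = False
) -> TrialTable:
    """Simulate one level of a preset design with its per-level fly count
    (the published designs used different fly counts per concentration;
    an explicit n_flies override takes precedence)."""
    preset = PRESETS.get(config.experiment)
    n_flies = config.n_flies
    if preset is not None and config.n_flies == preset.n_flies:
        n_flies = PRESET_FLIES_PER_LEVEL.get(config.experiment, {}).get(level, n_flies)
    protocols = build_protocols(config.experiment, level, seed=config.seed)
    pad_post = 0.2 if config.experiment == "fig4" else 0.5
    return simulate_experiment(
        protocols,
        config.sensillum_params(),
        n_flies=n_flies,
        n_trials=config.n_trials,
        seed=config.seed,
        synthesize=synthesize,
        pad_post=pad_post,
    )


def fig2_analysis(trials: TrialTable) -> dict:
    """Paired t-tests of transient rates (0.1-0.35 s window) with vs.
    without the incognate odorant, per unit."""
    table = response_table(trials, metrics=("window_mean_rate",))
    level = trials.trials[0].protocol.level
    out = {"level": level, "tests": [], "per_fly": None}
    per_fly_rows = []
    for unit in ("A", "B"):
        alone_label = unit
        mixed_label = f"{unit} on {'B' if unit == 'A' else 'A'}"
        sub = table[(table["unit"] == unit)]
        per_fly = sub.groupby(["stimulus_id", "fly_id"])["value"].mean().unstack(0)
        alone = per_fly[alone_label].to_numpy()
        mixed = per_fly[mixed_label].to_numpy()
        res = paired_t_test(alone, mixed, label=f"{unit}: alone vs with incognate ({level})")
        out["tests"].append(res)
        for fly, (a, m) in enumerate(zip(alone, mixed)):
            per_fly_rows.append(
                {"unit": unit, "level": level, "fly_id": fly, "alone": a, "with_incognate": m}
            )
    out["per_fly"] = pd.DataFrame(per_fly_rows)
    return out


def fig4_analysis(trials: TrialTable, q: float = 20.0) -> dict:
    """Victor-Purpura distance groups over the 10-s fluctuating window and
    Bonferroni-corrected two-sided U tests."""
    groups_df = dvp_comparison_groups(trials, q=q, window=(0.0, 10.0))
    tests = {}
    medians = {}
    for unit in ("A", "B"):
        sub = groups_df[groups_df["unit"] == unit]
        groups = {pair: grp["d_vp"].to_numpy() for pair, grp in sub.groupby("pair")}
        comparisons = [c for c in DVP_COMPARISONS[unit] if c[0] in groups and c[1] in groups]
        tests[unit] = utest_bonferroni(groups, comparisons)
        medians[unit] = {pair: float(np.median(v)) for pair, v in groups.items()}
    return {"groups": groups_df, "tests": tests, "medians": medians}


def _test_results_json(results) -> list[dict]:
    return [dataclasses.asdict(r) for r in results]


def run_experiment(config: RunConfig, out_dir: str | Path | None = None) -> RunManifest:
    """Execute one preset end to end and write all artifacts + manifest."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict())
    kernel = KernelParams(sigma=config.sigma_ms / 1000.0)

    tables: dict[str, TrialTable] = {}
    with StageTimer(manifest, "simulate", out) as st:
        for level in config.levels:
            trials = simulate_preset(config, level, synthesize=config.use_sorting)
            tables[level] = trials
            path = st.register(out / f"spikes_{config.experiment}_{level}.csv")
            write_spike_csv(trials, path)

    if config.use_sorting:
        with StageTimer(manifest, "sort", out) as st:
            for level in list(tables):
                tables[level] = sort_trial_table(tables[level])
                path = st.register(out / f"spikes_sorted_{config.experiment}_{level}.csv")
                write_spike_csv(tables[level], path)

    with StageTimer(manifest, "stats", out) as st:
        summary: dict = {"experiment": config.experiment, "seed": config.seed,
                         "q": config.q, "sigma_ms": config.sigma_ms}
        for level, trials in tables.items():
            if config.experiment == "fig2":
                res = fig2_analysis(trials)
                res["per_fly"].to_csv(
                    st.register(out / f"fig2_per_fly_{level}.csv"), index=False
                )
                summary[level] = {"tests": _test_results_json(res["tests"])}
            elif config.experiment == "fig3":
                res_units = {}
                for unit in ("A", "B"):
                    res = asynchrony_analysis(trials, unit=unit, kernel=kernel)
                    res["battery"].to_csv(
                        st.register(out / f"fig3_battery_{unit}_{level}.csv"), index=False
                    )
                    res_units[unit] = {
                        "window": res["window"],
                        "regression": {
                            "slope": res["regression"].slope,
                            "r2": res["regression"].r2,
                            "p": res["regression"].p,
                        },
                    }
                summary[level] = res_units
            elif config.experiment == "fig4":
                res = fig4_analysis(trials, q=config.q)
                res["groups"].to_csv(
                    st.register(out / f"fig4_dvp_groups_{level}.csv"), index=False
                )
                summary[level] = {
                    "medians": res["medians"],
                    "tests": {u: _test_results_json(t) for u, t in res["tests"].items()},
                }
        spath = st.register(out / "summary.json")
        with open(spath, "w") as fh:
            json.dump(summary, fh, indent=1, default=float)

    config.to_yaml(out / "config.yaml")
    manifest.write(out / "manifest.json")
    return manifest


def preset_config(name: str, **overrides) -> RunConfig:
    """A copy of a named preset with field overrides applied."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return dataclasses.replace(PRESETS[name], **overrides)
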