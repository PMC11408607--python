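"""Run configuration, spike-table file I/O, and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .sensillum import SensillumParams, SpikeTrain, Trial, TrialTable
from .stimuli import StimulusProtocol

SPIKE_CSV_COLUMNS = [
    "fly_id",
    "stimulus_id",
    "mixture_mode",
    "onset_asynchrony_ms",
    "level",
    "trial",
    "unit",
    "spike_time_s",
]


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Configuration of one end-to-end reproduction run."""

    experiment: str = "fig3"  # fig2 | fig3 | fig4 | custom
    seed: int = 0
    n_flies: int = 8
    n_trials: int = 10
    levels: tuple[str, ...] = ("low",)
    sigma_ms: float = 50.0
    q: float = 20.0
    use_sorting: bool = False
    out_dir: str = "results/run"
    sensillum_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment not in ("fig2", "fig3", "fig4", "custom"):
            raise ConfigError(f"unknown experiment {self.experiment!r}")
        if self.n_flies < 1 or self.n_trials < 1:
            raise ConfigError("n_flies and n_trials must be >= 1")
        if self.sigma_ms <= 0 or self.q < 0:
            raise ConfigError("sigma_ms must be > 0 and q >= 0")
        for lvl in self.levels:
            if lvl not in ("low", "high"):
                raise ConfigError(f"unknown concentration level {lvl!r}")

    def sensillum_params(self) -> SensillumParams:
        return dataclasses.replace(SensillumParams(), **self.sensillum_overrides)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["levels"] = list(self.levels)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["levels"] = tuple(d.get("levels", ("low",)))
        return cls(**d)


#: Experiment designs of the three figure-style reproductions:
#: fig2 — background+pulse at both concentrations (8 flies low / 6 high,
#: 3 trials); fig3 — 15 onset-asynchrony stimuli at low concentration
#: (8 flies, 10 trials); fig4 — 5 fluctuating 10-s stimuli (6 flies low /
#: 8 high, 5 trials).
PRESETS: dict[str, RunConfig] = {
    "fig2": RunConfig(experiment="fig2", n_flies=8, n_trials=3, levels=("low", "high")),
    "fig3": RunConfig(experiment="fig3", n_flies=8, n_trials=10, levels=("low",)),
    "fig4": RunConfig(experiment="fig4", n_flies=8, n_trials=5, levels=("high",)),
}

#: Fly counts the designs used per concentration level where they differ.
PRESET_FLIES_PER_LEVEL = {"fig2": {"low": 8, "high": 6}, "fig4": {"low": 6, "high": 8}}


def write_spike_csv(trials: TrialTable, path) -> None:
    """Long-format spike CSV (one row per spike, microsecond precision)."""
    df = trials.to_dataframe()
    df["spike_time_s"] = df["spike_time_s"].round(6)
    df.to_csv(path, index=False)


def read_spike_csv(path, protocols: dict[str, StimulusProtocol]) -> TrialTable:
    """Inverse of :func:`write_spike_csv`.

    ``protocols`` supplies the stimulus definitions the CSV refers to.
    Unsorted spike times are sorted with a warning; missing required
    columns raise a schema error naming the column.
    """
    df = pd.read_csv(path)
    for col in SPIKE_CSV_COLUMNS:
        if col not in df.columns:
            raise ConfigError(f"spike CSV is missing required column {col!r}")
    table = TrialTable(protocols=dict(protocols))
    keys = df.groupby(["fly_id", "stimulus_id", "trial"], sort=True)
    for (fly, stim, trial), grp in keys:
        if stim not in protocols:
            raise ConfigError(f"spike CSV references unknown stimulus {stim!r}")
        trains = {}
        for unit in ("A", "B"):
            times = grp[grp["unit"] == unit]["spike_time_s"].to_numpy(dtype=float)
            if times.size and np.any(np.diff(times) < 0):
                warnings.warn(f"unsorted spike times for {(fly, stim, trial)}; sorting")
                times = np.sort(times)
            trains[unit] = SpikeTrain(
                times, unit=unit, fly_id=int(fly), stimulus_id=str(stim), trial_index=int(trial)
            )
        table.trials.append(
            Trial(
                fly_id=int(fly),
                stimulus_id=str(stim),
                trial_index=int(trial),
                protocol=protocols[stim],
                trains=trains,
            )
        )
    return table


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record of a run: config snapshot, per-stage timing
    and output-file hashes.  Written atomically at run end."""

    config: dict
    version: str = "0.1.0"
    stages: dict = field(default_factory=dict)  # stage -> {seconds, outputs: {file: hash}}

    def add_stage(self, name: str, seconds: float, outputs: dict[str, str]) -> None:
        self.stages[name] = {"seconds": round(seconds, 3), "outputs": outputs}

    def write(self, path) -> None:
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        with open(tmp, "w") as fh:
            json.dump({"config": self.config, "version": self.version, "stages": self.stages}, fh, indent=1)
        tmp.rename(path)

    def verify(self, base_dir) -> bool:
        """Re-hash every recorded output file; True if all match."""
        for stage in self.stages.values():
            for fname, digest in stage["outputs"].items():
                if file_sha256(Path(base_dir) / fname) != digest:
                    return False
        return True


class StageTimer:
    def __init__(self, manifest: RunManifest, name: str, base_dir: Path):
        self.manifest, self.name, self.base = manifest, name, Path(base_dir)
        self.outputs: list[Path] = []

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def register(self, path: Path) -> Path:
        self.outputs.append(Path(path))
        return Path(path)

    def __exit__(self, exc_type, exc, tb):
        if exc_type is not None:
            raise RuntimeError(f"stage {self.name!r} failed") from exc
        hashes = {str(p.relative_to(self.base)): file_sha256(p) for p in self.outputs}
        self.manifest.add_stage(self.name, time.perf_counter() - self.t0, hashes)
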