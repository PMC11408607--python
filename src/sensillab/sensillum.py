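"""Synthetic two-ORN sensillum: ground-truth spike trains and voltage traces.

Models the ab3 sensillum of *Drosophila melanogaster*, which houses a large
"A" neuron (ab3A, cognate odorant methyl hexanoate) and a small "B" neuron
(ab3B, cognate odorant 2-heptanone).  The two neurons share an electrically
insulated lymph space and suppress each other nonsynaptically (ephaptic
inhibition); the suppression is reciprocal but asymmetric — the large A
neuron inhibits B more strongly than vice versa — and grows with odorant
concentration.

The simulation pipeline per trial is::

    valve commands -> concentration -> transduction (Hill + adaptation)
        -> ephaptic coupling (subtractive, rectified, instantaneous)
        -> inhomogeneous Poisson spiking with absolute refractoriness
        -> (optional) extracellular-style voltage with two spike-amplitude
           classes whose amplitudes decline with local firing rate

Transduction defaults are calibrated so a low-concentration 0.5-s pulse
yields a transient peak of ~70-75 spikes/s and a sustained rate of
~21-25 spikes/s two seconds into a constant stimulus, with the
corresponding high-concentration bands of ~120-230 and ~35-52 spikes/s.

Everything is deterministic given the master seed; seeding is hierarchical
(experiment -> fly -> stimulus -> trial) so enlarging an experiment does not
perturb previously generated trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .stimuli import ConcentrationTrace, StimulusProtocol, valve_to_concentration

UNITS = ("A", "B")

#: Odorant concentration fractions delivered by the olfactometer.
LEVEL_CONC = {"high": 1.43e-3, "low": 1.43e-6}


class SimulationError(ValueError):
    """Invalid simulation parameters."""


@dataclass(frozen=True)
class ORNParams:
    """Single-ORN transduction, spiking and waveform parameters.

    The drive (intended instantaneous firing rate, spikes/s) in response to
    its cognate odorant at concentration fraction ``c`` is::

        u(c)   = max_rate * c**hill_n / (c**hill_n + half_conc**hill_n)
        a'(t)  = (adapt_strength * u - a) / adapt_tau        (adaptation)
        drive  = baseline_rate + max(0, u - a)

    so a concentration step produces a transient peak of ``~u`` that relaxes
    to a sustained plateau of ``u * (1 - adapt_strength)``.  Incognate
    odorants produce no drive beyond baseline.
    """

    baseline_rate: float = 2.0
    max_rate: float = 1000.0
    half_conc: float = 3.3e-6
    hill_n: float = 0.362
    adapt_tau: float = 0.035
    adapt_strength: float = 0.9506
    refractory: float = 0.0015
    spike_amplitude: float = 3.0  # mV
    spike_width: float = 2.0  # ms
    amp_rate_decay: float = 0.0015  # per spikes/s

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.max_rate < 0:
            raise SimulationError("rates must be >= 0")
        if not 0.0 <= self.adapt_strength <= 1.0:
            raise SimulationError("adapt_strength must be in [0, 1]")
        if self.refractory <= 0:
            raise SimulationError("refractory must be > 0")


#: ab3B: smaller spikes, narrower waveform; same transduction calibration.
DEFAULT_ORN_B = ORNParams(spike_amplitude=1.0, spike_width=1.5)


@dataclass(frozen=True)
class SensillumParams:
    """Parameters of the coupled two-ORN sensillum.

    ``g_ab`` scales how strongly A's suprabaseline drive suppresses B;
    ``g_ba`` the reverse.  Asymmetry ``g_ab > g_ba`` reflects the larger
    A neuron exerting stronger and receiving weaker ephaptic inhibition.
    ``fly_jitter_cv`` is the coefficient of variation of the lognormal
    per-fly jitter applied to sensitivity and coupling parameters.
    """

    orn_a: ORNParams = field(default_factory=ORNParams)
    orn_b: ORNParams = field(default_factory=lambda: DEFAULT_ORN_B)
    g_ab: float = 0.5
    g_ba: float = 0.1875
    coupling_threshold: float = 30.0  # spikes/s of suprabaseline drive
    noise_sd: float = 0.1  # mV
    sampling_rate: float = 1000.0  # drive/concentration sampling, Hz
    trace_sampling_rate: float = 10000.0  # voltage trace sampling, Hz
    fly_jitter_cv: float = 0.3
    trial_jitter_cv: float = 0.1
    tau_rise: float = 0.010
    tau_fall: float = 0.015

    def __post_init__(self) -> None:
        if self.g_ab < 0 or self.g_ba < 0:
            raise SimulationError("coupling gains must be >= 0")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")

    def orn(self, unit: str) -> ORNParams:
        return {"A": self.orn_a, "B": self.orn_b}[unit]


@dataclass(frozen=True)
class DriveTrace:
    """Latent instantaneous firing rate (spikes/s); stands in for the
    generator potential."""

    sampling_rate: float
    values: np.ndarray
    t0: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sampling_rate - self.t0


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (s, relative to stimulus onset) of one unit."""

    spike_times: np.ndarray
    unit: str = "A"
    fly_id: int = 0
    stimulus_id: str = ""
    trial_index: int = 0

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", st)
        if st.size and np.any(np.diff(st) < 0):
            raise SimulationError("spike_times must be sorted")

    def __len__(self) -> int:
        return int(self.spike_times.size)


@dataclass(frozen=True)
class RecordingTrace:
    """Synthetic extracellular voltage with retained ground truth."""

    sampling_rate: float
    voltage: np.ndarray
    t0: float = 0.0
    ground_truth: tuple[tuple[float, str], ...] = ()

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.voltage.size) / self.sampling_rate - self.t0


@dataclass(frozen=True)
class Trial:
    fly_id: int
    stimulus_id: str
    trial_index: int
    protocol: StimulusProtocol
    trains: dict[str, SpikeTrain]
    trace: RecordingTrace | None = None


@dataclass
class TrialTable:
    """All trials of a simulated multi-fly experiment."""

    trials: list[Trial] = field(default_factory=list)
    protocols: dict[str, StimulusProtocol] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format spike table (one row per spike)."""
        rows = []
        for tr in self.trials:
            proto = tr.protocol
            for unit, train in tr.trains.items():
                for t in train.spike_times:
                    rows.append(
                        {
                            "fly_id": tr.fly_id,
                            "stimulus_id": tr.stimulus_id,
                            "mixture_mode": proto.mixture_mode,
                            "onset_asynchrony_ms": proto.onset_asynchrony_ms,
                            "level": proto.level,
                            "trial": tr.trial_index,
                            "unit": unit,
                            "spike_time_s": t,
                        }
                    )
        return pd.DataFrame(
            rows,
            columns=[
                "fly_id",
                "stimulus_id",
                "mixture_mode",
                "onset_asynchrony_ms",
                "level",
                "trial",
                "unit",
                "spike_time_s",
            ],
        )


def transduce(conc: ConcentrationTrace, p: ORNParams, cognate: bool = True) -> DriveTrace:
    """Odorant concentration -> latent firing-rate drive for one ORN.

    Hill activation followed by first-order subtractive adaptation; see
    :class:`ORNParams`.  An incognate odorant leaves the ORN at baseline.
    """
    c = np.asarray(conc.values, dtype=float)
    if not cognate:
        return DriveTrace(conc.sampling_rate, np.full(c.size, p.baseline_rate), conc.t0)
    cn = np.power(np.maximum(c, 0.0), p.hill_n)
    u = p.max_rate * cn / (cn + p.half_conc**p.hill_n)
    # adaptation state: exponential low-pass of adapt_strength * u
    beta = np.exp(-1.0 / (conc.sampling_rate * p.adapt_tau))
    a = lfilter([1.0 - beta], [1.0, -beta], p.adapt_strength * u)
    drive = p.baseline_rate + np.maximum(0.0, u - a)
    return DriveTrace(conc.sampling_rate, drive, conc.t0)


def ephaptic_couple(
    drive_a: DriveTrace, drive_b: DriveTrace, s: SensillumParams
) -> tuple[DriveTrace, DriveTrace]:
    """Apply instantaneous, rectified subtractive ephaptic coupling.

    Each neuron's drive is reduced in proportion to how far the other's
    uncoupled drive exceeds its baseline plus an activation threshold
    ``theta`` (``coupling_threshold``)::

        B'(t) = max(0, B(t) - g_ab * max(0, A(t) - baseline_A - theta))
        A'(t) = max(0, A(t) - g_ba * max(0, B(t) - baseline_B - theta))

    The threshold reflects that weak activity draws too little
    transepithelial current to suppress the neighbor measurably; only
    vigorous (transient or strong sustained) activity couples.  Both
    reductions are computed from the uncoupled drives (no fixed-point
    iteration) and act sample-synchronously: ephaptic interaction in the
    sensillum lymph is fast compared to the 1-ms drive resolution.
    """
    if drive_a.values.size != drive_b.values.size:
        raise SimulationError("drive traces must have equal length")
    if drive_a.sampling_rate != drive_b.sampling_rate:
        raise SimulationError("drive traces must share a sampling rate")
    theta = s.coupling_threshold
    supra_a = np.maximum(0.0, drive_a.values - s.orn_a.baseline_rate - theta)
    supra_b = np.maximum(0.0, drive_b.values - s.orn_b.baseline_rate - theta)
    new_a = np.maximum(0.0, drive_a.values - s.g_ba * supra_b)
    new_b = np.maximum(0.0, drive_b.values - s.g_ab * supra_a)
    return (
        DriveTrace(drive_a.sampling_rate, new_a, drive_a.t0),
        DriveTrace(drive_b.sampling_rate, new_b, drive_b.t0),
    )


def generate_spikes(
    drive: DriveTrace,
    refractory: float,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    unit: str = "A",
    **train_meta,
) -> SpikeTrain:
    """Inhomogeneous Poisson spiking with an absolute refractory period.

    Realized by thinning a homogeneous Poisson process at the drive maximum;
    candidates within ``refractory`` of the last accepted spike are dropped,
    which makes the output an exact dead-time-modulated Poisson process
    (constant drive ``r`` realizes ``r / (1 + r * refractory)`` spikes/s).
    """
    if np.any(drive.values < 0):
        raise SimulationError("drive must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    duration = drive.values.size / drive.sampling_rate
    rmax = float(drive.values.max(initial=0.0))
    if rmax <= 0 or duration <= 0:
        return SpikeTrain(np.empty(0), unit=unit, **train_meta)
    n_cand = rng.poisson(rmax * duration)
    cand = np.sort(rng.uniform(0.0, duration, n_cand))
    accept_u = rng.uniform(0.0, 1.0, n_cand)
    idx = np.minimum((cand * drive.sampling_rate).astype(int), drive.values.size - 1)
    keep = accept_u < drive.values[idx] / rmax
    times = cand[keep]
    out = []
    last = -np.inf
    for t in times:
        if t - last >= refractory:
            out.append(t)
            last = t
    return SpikeTrain(np.asarray(out) - drive.t0, unit=unit, **train_meta)


def _biphasic_waveform(width_ms: float, sampling_rate: float) -> np.ndarray:
    """Unit-peak biphasic spike waveform (sharp positive lobe, slower trough)."""
    n = max(int(round(width_ms / 1000.0 * sampling_rate)), 4)
    t = np.linspace(0.0, 1.0, n)
    w = np.sin(2.0 * np.pi * t) * np.exp(-3.0 * t)
    return w / np.abs(w).max()


def _causal_local_rate(times: np.ndarray, tau: float = 0.050) -> np.ndarray:
    """Causal exponential-window firing-rate estimate at each spike time,
    from strictly preceding spikes of the same unit."""
    rate = np.zeros(times.size)
    state = 0.0
    last = None
    for i, t in enumerate(times):
        if last is not None:
            state = state * np.exp(-(t - last) / tau)
        rate[i] = state / tau
        state += 1.0
        last = t
    return rate


def synthesize_trace(
    trains: Mapping[str, SpikeTrain],
    s: SensillumParams,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    duration: float | None = None,
    t0: float = 0.0,
) -> RecordingTrace:
    """Render spike trains into an extracellular-style voltage trace.

    Each spike adds a biphasic waveform whose amplitude declines with the
    unit's local firing rate, ``amp = spike_amplitude * exp(-amp_rate_decay
    * local_rate)`` — emulating the prominent activity-dependent shrinkage
    of spike shapes in single-sensillum recordings.  The local rate is
    estimated causally from preceding spikes only.  White Gaussian noise of
    SD ``noise_sd`` is added; ground-truth (time, unit) events are retained.
    """
    fs = s.trace_sampling_rate
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    all_times = [tr.spike_times + t0 for tr in trains.values()]
    if duration is None:
        tmax = max((t.max() for t in all_times if t.size), default=0.0)
        duration = tmax + 0.01
    for unit in trains:
        width_s = s.orn(unit).spike_width / 1000.0
        if fs < 4.0 / width_s:
            raise SimulationError("trace sampling rate too low for spike width")
    n = int(round(duration * fs))
    v = rng.normal(0.0, s.noise_sd, n)
    truth: list[tuple[float, str]] = []
    for unit, train in trains.items():
        p = s.orn(unit)
        wf = _biphasic_waveform(p.spike_width, fs)
        times = train.spike_times + t0
        if np.any((times < 0) | (times > duration)):
            raise SimulationError("spike outside trace duration")
        rates = _causal_local_rate(times)
        amps = p.spike_amplitude * np.exp(-p.amp_rate_decay * rates)
        for t, a in zip(times, amps):
            i0 = int(round(t * fs))
            i1 = min(i0 + wf.size, n)
            v[i0:i1] += a * wf[: i1 - i0]
            truth.append((t - t0, unit))
    truth.sort()
    return RecordingTrace(fs, v, t0=t0, ground_truth=tuple(truth))


def _jitter_params(s: SensillumParams, rng: np.random.Generator) -> SensillumParams:
    """Per-fly lognormal jitter (unit mean, CV = fly_jitter_cv) on ORN
    sensitivity and on the coupling gains."""
    cv = s.fly_jitter_cv
    if cv <= 0:
        return s
    sigma = np.sqrt(np.log(1.0 + cv**2))
    mu = -0.5 * sigma**2

    def factor() -> float:
        return float(rng.lognormal(mu, sigma))

    return replace(
        s,
        orn_a=replace(s.orn_a, max_rate=s.orn_a.max_rate * factor()),
        orn_b=replace(s.orn_b, max_rate=s.orn_b.max_rate * factor()),
        g_ab=s.g_ab * factor(),
        g_ba=s.g_ba * factor(),
    )


def _trial_drift(s: SensillumParams, rng: np.random.Generator) -> SensillumParams:
    """Per-trial recording-state drift: one lognormal gain factor (unit mean,
    CV = trial_jitter_cv) applied to both ORNs' sensitivity, emulating slow
    electrode and physiological-state fluctuations across repetitions."""
    cv = s.trial_jitter_cv
    if cv <= 0:
        return s
    sigma = np.sqrt(np.log(1.0 + cv**2))
    f = float(rng.lognormal(-0.5 * sigma**2, sigma))
    return replace(
        s,
        orn_a=replace(s.orn_a, max_rate=s.orn_a.max_rate * f),
        orn_b=replace(s.orn_b, max_rate=s.orn_b.max_rate * f),
    )


COGNATE = {"A": "A", "B": "B"}  # channel -> unit it drives


def simulate_trial(
    protocol: StimulusProtocol,
    s: SensillumParams,
    seed: int | np.random.SeedSequence = 0,
    pad_pre: float = 0.5,
    pad_post: float = 0.5,
    synthesize: bool = False,
    fly_id: int = 0,
    trial_index: int = 0,
) -> Trial:
    """One trial: concentration -> drives -> coupling -> spikes (-> voltage).

    Spike times are reported relative to the protocol's time origin (leading
    valve opening); the simulated window is ``[-pad_pre - time_origin,
    duration - time_origin + pad_post]``.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(c) for c in ss.spawn(3)]
    fs = s.sampling_rate
    peak = LEVEL_CONC[protocol.level]
    n_pre = int(round(pad_pre * fs))
    t0 = pad_pre + protocol.time_origin
    drives: dict[str, DriveTrace] = {}
    for ch in ("A", "B"):
        conc = valve_to_concentration(
            protocol.channels[ch],
            peak_conc=peak,
            tau_rise=s.tau_rise,
            tau_fall=s.tau_fall,
            sampling_rate=fs,
            pad=pad_post,
        )
        values = np.concatenate([np.zeros(n_pre), conc.values])
        conc_padded = ConcentrationTrace(fs, values, t0=t0)
        unit = COGNATE[ch]
        drives[unit] = transduce(conc_padded, s.orn(unit), cognate=True)
    drive_a, drive_b = ephaptic_couple(drives["A"], drives["B"], s)
    trains = {
        "A": generate_spikes(
            drive_a, s.orn_a.refractory, rngs[0], unit="A",
            fly_id=fly_id, stimulus_id=protocol.label, trial_index=trial_index,
        ),
        "B": generate_spikes(
            drive_b, s.orn_b.refractory, rngs[1], unit="B",
            fly_id=fly_id, stimulus_id=protocol.label, trial_index=trial_index,
        ),
    }
    trace = None
    if synthesize:
        trace = synthesize_trace(
            trains, s, rngs[2], duration=drive_a.values.size / fs, t0=t0
        )
    return Trial(
        fly_id=fly_id,
        stimulus_id=protocol.label,
        trial_index=trial_index,
        protocol=protocol,
        trains=trains,
        trace=trace,
    )


def simulate_experiment(
    protocols: Mapping[str, StimulusProtocol] | Iterable[StimulusProtocol],
    s: SensillumParams,
    n_flies: int,
    n_trials: int,
    seed: int = 0,
    synthesize: bool = False,
    pad_pre: float = 0.5,
    pad_post: float = 0.5,
) -> TrialTable:
    """Simulate a whole multi-fly experiment.

    Each simulated fly gets jittered sensillum parameters; every
    (fly, stimulus, trial) combination is simulated with its own
    deterministic random stream derived from ``(seed, fly, stimulus,
    trial)``.
    """
    if n_flies < 1 or n_trials < 1:
        raise SimulationError("n_flies and n_trials must be >= 1")
    if not isinstance(protocols, Mapping):
        protocols = {p.label or f"stim{i}": p for i, p in enumerate(protocols)}
    table = TrialTable(protocols=dict(protocols))
    for fly in range(n_flies):
        fly_rng = np.random.default_rng(np.random.SeedSequence((seed, 1, fly)))
        s_fly = _jitter_params(s, fly_rng)
        for k, (label, proto) in enumerate(protocols.items()):
            for trial in range(n_trials):
                trial_seed = np.random.SeedSequence((seed, 2, fly, k, trial))
                s_trial = _trial_drift(s_fly, np.random.default_rng((seed, 3, fly, k, trial)))
                table.trials.append(
                    simulate_trial(
                        proto,
                        s_trial,
                        seed=trial_seed,
                        pad_pre=pad_pre,
                        pad_post=pad_post,
                        synthesize=synthesize,
                        fly_id=fly,
                        trial_index=trial,
                    )
                )
    return table
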