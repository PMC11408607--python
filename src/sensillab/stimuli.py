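"""Odorant stimulus design for two-channel sensillum experiments.

Stimuli are defined as valve command sequences for two odorant channels
(A = methyl hexanoate, the cognate ligand of the large ab3A neuron;
B = 2-heptanone, the cognate ligand of the small ab3B neuron).  A valve
sequence is stored as its exact toggle times plus the initial state, so a
dense binary trace can be derived at any sampling rate without loss.

The module builds the four stimulus families used throughout the analysis:

* single square pulses,
* a pulse of one odorant on a sustained background of the other,
* pulse pairs with a controlled onset asynchrony (0-96 ms, either order),
* 10-s pseudorandom fluctuating mixtures driven by Poisson valve switching,
  in correlated (both channels share one time course) and uncorrelated
  (independent time courses) variants.

It also converts valve commands into photoionization-detector-like
concentration traces (asymmetric first-order dynamics) and checks the
air-dilution arithmetic of the olfactometer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

CHANNELS = ("A", "B")

#: Odorant identity per channel.
ODORANTS = {"A": "MHXE", "B": "HEPN"}

#: Default mean inter-toggle interval of the pseudorandom valve switching (s).
DEFAULT_MEAN_INTERVAL = 0.050

#: Default duration of a fluctuating stimulus segment (s).
DEFAULT_FLUCT_DURATION = 10.0

#: Onset-asynchrony grid used in the pulse-pair experiments (ms).
ASYNCHRONY_GRID_MS = (0, 3, 6, 12, 24, 48, 96)


class StimulusError(ValueError):
    """Invalid stimulus parameters."""


@dataclass(frozen=True)
class ValveSequence:
    """Timed valve states of one odorant channel.

    ``toggle_times`` are the instants (s) at which the valve flips state,
    strictly increasing within ``[0, duration)``; ``initial_state`` is the
    state before the first toggle (False = closed).  The state at any time
    follows by counting toggles.
    """

    toggle_times: np.ndarray
    duration: float
    channel: str
    initial_state: bool = False

    def __post_init__(self) -> None:
        tt = np.asarray(self.toggle_times, dtype=float)
        object.__setattr__(self, "toggle_times", tt)
        if self.channel not in CHANNELS:
            raise StimulusError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        if self.duration < 0:
            raise StimulusError("duration must be >= 0")
        if tt.size:
            if np.any(np.diff(tt) <= 0):
                raise StimulusError("toggle_times must be strictly increasing")
            if tt[0] < 0 or tt[-1] >= self.duration:
                raise StimulusError("toggle_times must lie in [0, duration)")

    def state_at(self, t: float) -> bool:
        """Valve state at time ``t`` (open = True)."""
        n = int(np.searchsorted(self.toggle_times, t, side="right"))
        return bool(self.initial_state ^ (n % 2))

    def to_dense(self, sampling_rate: float) -> np.ndarray:
        """Dense boolean state trace sampled at ``sampling_rate`` Hz."""
        n = int(round(self.duration * sampling_rate))
        t = np.arange(n) / sampling_rate
        counts = np.searchsorted(self.toggle_times, t, side="right")
        return (counts % 2).astype(bool) ^ self.initial_state

    def open_time(self) -> float:
        """Total time (s) the valve is open."""
        edges = np.concatenate(([0.0], self.toggle_times, [self.duration]))
        states = (self.initial_state + np.arange(edges.size - 1)) % 2
        return float(np.sum(np.diff(edges)[states == 1]))

    def shifted(self, dt: float, duration: float | None = None) -> "ValveSequence":
        """Copy with all toggles delayed by ``dt`` (>= 0)."""
        return ValveSequence(
            toggle_times=self.toggle_times + dt,
            duration=self.duration + dt if duration is None else duration,
            channel=self.channel,
            initial_state=self.initial_state,
        )


@dataclass(frozen=True)
class StimulusProtocol:
    """A complete two-channel stimulus.

    ``time_origin`` is the instant, on the sequence timeline, that counts
    as t = 0 for analysis: the opening of the leading/pulse valve.  All
    response windows downstream are expressed relative to it.
    """

    channels: dict[str, ValveSequence]
    kind: Literal["pulse", "background_pulse", "asynchrony_pair", "fluctuating"]
    level: Literal["high", "low"] = "low"
    onset_asynchrony_ms: float | None = None
    mixture_mode: Literal["A", "B", "AB_i", "AB_A", "AB_B"] | None = None
    time_origin: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if set(self.channels) != set(CHANNELS):
            raise StimulusError("protocol must define channels A and B")
        if self.onset_asynchrony_ms is not None and self.kind != "asynchrony_pair":
            raise StimulusError("onset_asynchrony only applies to asynchrony_pair stimuli")
        if self.mixture_mode is not None and self.kind != "fluctuating":
            raise StimulusError("mixture_mode only applies to fluctuating stimuli")
        durs = {seq.duration for seq in self.channels.values()}
        if len(durs) != 1:
            raise StimulusError("channel sequences must share one duration")

    @property
    def duration(self) -> float:
        return self.channels["A"].duration

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "level": self.level,
            "onset_asynchrony_ms": self.onset_asynchrony_ms,
            "mixture_mode": self.mixture_mode,
            "time_origin_s": self.time_origin,
            "label": self.label,
            "channels": [
                {
                    "channel": ch,
                    "initial_state": "open" if seq.initial_state else "closed",
                    "toggle_times_s": seq.toggle_times.tolist(),
                    "duration_s": seq.duration,
                }
                for ch, seq in sorted(self.channels.items())
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        channels = {
            c["channel"]: ValveSequence(
                toggle_times=np.asarray(c["toggle_times_s"], dtype=float),
                duration=c["duration_s"],
                channel=c["channel"],
                initial_state=c["initial_state"] == "open",
            )
            for c in d["channels"]
        }
        return cls(
            channels=channels,
            kind=d["kind"],
            level=d["level"],
            onset_asynchrony_ms=d.get("onset_asynchrony_ms"),
            mixture_mode=d.get("mixture_mode"),
            time_origin=d.get("time_origin_s", 0.0),
            label=d.get("label", ""),
        )

    @classmethod
    def from_json(cls, path) -> "StimulusProtocol":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class FlowConfig:
    """Olfactometer flow rates (mL/min) and dilution-stage layout."""

    odorant_flow: float = 3.0
    dilution_air_flow: float = 297.0
    n_dilution_stages: int = 1
    n_channels: int = 2
    carrier_flow: float = 1500.0
    #: If set, pins the final dilution fraction (used for the low-concentration
    #: setting, whose serial-dilution bookkeeping is hardware-specific).
    final_fraction_override: float | None = None

    def __post_init__(self) -> None:
        if min(self.odorant_flow, self.dilution_air_flow, self.carrier_flow) < 0:
            raise StimulusError("flows must be >= 0")
        if self.n_channels < 1 or self.n_dilution_stages < 1:
            raise StimulusError("n_channels and n_dilution_stages must be >= 1")


@dataclass(frozen=True)
class ConcentrationTrace:
    """Dimensionless odorant concentration fraction versus time.

    Emulates a photoionization-detector measurement downstream of the valve.
    ``t0`` marks the analysis time origin (leading valve opening) on the
    sample timeline, i.e. sample ``i`` sits at ``i / sampling_rate - t0``
    relative to stimulus onset.
    """

    sampling_rate: float
    values: np.ndarray
    t0: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sampling_rate - self.t0

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.times, self.values])
        np.savetxt(path, arr, delimiter=",", header="time_s,concentration", comments="")


def generate_poisson_valve_sequence(
    duration: float,
    mean_interval: float = DEFAULT_MEAN_INTERVAL,
    seed: int | np.random.SeedSequence = 0,
    channel: str = "A",
) -> ValveSequence:
    """Pseudorandom valve switching: toggles form a Poisson point process.

    Inter-toggle intervals are i.i.d. exponential with mean ``mean_interval``
    (default 50 ms), truncated to ``[0, duration)``.  Deterministic for a
    given seed.
    """
    if mean_interval <= 0:
        raise StimulusError("mean_interval must be > 0")
    if duration < 0:
        raise StimulusError("duration must be >= 0")
    rng = np.random.default_rng(seed)
    toggles = []
    t = 0.0
    while True:
        t += rng.exponential(mean_interval)
        if t >= duration:
            break
        toggles.append(t)
    return ValveSequence(
        toggle_times=np.asarray(toggles), duration=duration, channel=channel
    )


def _closed(channel: str, duration: float) -> ValveSequence:
    return ValveSequence(toggle_times=np.empty(0), duration=duration, channel=channel)


def _single_pulse(channel: str, t_open: float, pulse_duration: float, duration: float) -> ValveSequence:
    return ValveSequence(
        toggle_times=np.asarray([t_open, t_open + pulse_duration]),
        duration=duration,
        channel=channel,
    )


def make_pulse_protocol(
    channel: str,
    pulse_duration: float = 0.5,
    level: str = "low",
    duration: float | None = None,
) -> StimulusProtocol:
    """Single 0.5-s-style square pulse on one channel, other channel closed."""
    if channel not in CHANNELS:
        raise StimulusError(f"unknown channel {channel!r}")
    if pulse_duration <= 0:
        raise StimulusError("pulse_duration must be > 0")
    if duration is None:
        duration = pulse_duration + 1.0
    other = "B" if channel == "A" else "A"
    return StimulusProtocol(
        channels={
            channel: _single_pulse(channel, 0.0, pulse_duration, duration),
            other: _closed(other, duration),
        },
        kind="pulse",
        level=level,
        label=channel,
    )


def make_asynchrony_protocol(
    dt_ms: float,
    leading: str = "A",
    pulse_duration: float = 0.5,
    level: str = "low",
    duration: float | None = None,
) -> StimulusProtocol:
    """Pulse pair with onset asynchrony ``dt_ms``; the leading valve opens at t=0.

    Label follows the leading-trailing notation, e.g. ``A96B`` = A leads B by
    96 ms.  ``onset_asynchrony_ms`` is signed: positive when A leads.
    """
    if dt_ms < 0:
        raise StimulusError("dt_ms must be >= 0")
    if leading not in CHANNELS:
        raise StimulusError(f"unknown channel {leading!r}")
    if pulse_duration <= 0:
        raise StimulusError("pulse_duration must be > 0")
    dt = dt_ms / 1000.0
    if duration is None:
        duration = pulse_duration + dt + 1.0
    trailing = "B" if leading == "A" else "A"
    if dt_ms == 0:
        leading, trailing = "A", "B"  # no leader at zero shift; canonical order
    signed = dt_ms if leading == "A" else -dt_ms
    return StimulusProtocol(
        channels={
            leading: _single_pulse(leading, 0.0, pulse_duration, duration),
            trailing: _single_pulse(trailing, dt, pulse_duration, duration),
        },
        kind="asynchrony_pair",
        level=level,
        onset_asynchrony_ms=signed,
        label=f"{leading}{dt_ms:g}{trailing}" if dt_ms else "A0B",
    )


def make_background_pulse_protocol(
    background_channel: str,
    pulse_channel: str,
    background_lead: float = 2.0,
    pulse_duration: float = 0.5,
    level: str = "high",
    tail: float = 1.0,
) -> StimulusProtocol:
    """Pulse of one odorant on a sustained background of the other.

    The background valve opens ``background_lead`` s (>= 2 s, so the
    background response is in its sustained phase) before the pulse valve;
    the pulse valve opening defines t = 0 (``time_origin``).  The background
    stays open to the end of the sequence.
    """
    if background_lead < 2.0:
        raise StimulusError("background_lead must be >= 2 s (sustained-phase requirement)")
    if background_channel == pulse_channel or {background_channel, pulse_channel} != set(CHANNELS):
        raise StimulusError("background and pulse channels must be A and B in some order")
    if pulse_duration <= 0:
        raise StimulusError("pulse_duration must be > 0")
    duration = background_lead + pulse_duration + tail
    bg = ValveSequence(
        toggle_times=np.asarray([0.0]), duration=duration, channel=background_channel
    )
    pulse = _single_pulse(pulse_channel, background_lead, pulse_duration, duration)
    return StimulusProtocol(
        channels={background_channel: bg, pulse_channel: pulse},
        kind="background_pulse",
        level=level,
        time_origin=background_lead,
        label=f"{pulse_channel} on {background_channel}",
    )


def make_fluctuating_mixture_set(
    duration: float = DEFAULT_FLUCT_DURATION,
    mean_interval: float = DEFAULT_MEAN_INTERVAL,
    seed_a: int = 1,
    seed_b: int = 2,
    level: str = "high",
) -> dict[str, StimulusProtocol]:
    """The five fluctuating stimuli: A, B, AB_i, AB_A, AB_B.

    Exactly two pseudorandom base sequences are drawn (one per seed).  The
    single-odorant stimuli A and B use their own base sequence; the
    uncorrelated mixture AB_i pairs them; the correlated mixtures AB_A and
    AB_B apply one base sequence to both channels.  Per-channel valve-open
    time is therefore conserved within each column, and the summed A+B open
    time matches across AB_i / AB_A / AB_B only in expectation (each
    correlated mixture doubles one base sequence).
    """
    if seed_a == seed_b:
        raise StimulusError("seed_a must differ from seed_b (else correlated == uncorrelated)")
    base_a = generate_poisson_valve_sequence(duration, mean_interval, seed_a, channel="A")
    base_b = generate_poisson_valve_sequence(duration, mean_interval, seed_b, channel="B")

    def as_channel(seq: ValveSequence, channel: str) -> ValveSequence:
        return ValveSequence(
            toggle_times=seq.toggle_times.copy(),
            duration=seq.duration,
            channel=channel,
            initial_state=seq.initial_state,
        )

    def proto(mode: str, seq_a: ValveSequence | None, seq_b: ValveSequence | None) -> StimulusProtocol:
        return StimulusProtocol(
            channels={
                "A": seq_a if seq_a is not None else _closed("A", duration),
                "B": seq_b if seq_b is not None else _closed("B", duration),
            },
            kind="fluctuating",
            level=level,
            mixture_mode=mode,
            label=mode,
        )

    return {
        "A": proto("A", base_a, None),
        "B": proto("B", None, base_b),
        "AB_i": proto("AB_i", base_a, base_b),
        "AB_A": proto("AB_A", base_a, as_channel(base_a, "B")),
        "AB_B": proto("AB_B", as_channel(base_b, "A"), base_b),
    }


def make_asynchrony_stimulus_grid(
    level: str = "low",
    pulse_duration: float = 0.5,
    grid_ms: tuple[int, ...] = ASYNCHRONY_GRID_MS,
    duration: float | None = None,
) -> dict[str, StimulusProtocol]:
    """The 15-stimulus onset-asynchrony design: each single odorant alone,
    the synchronous mixture, and every nonzero asynchrony in both orders
    (A leading and B leading)."""
    if duration is None:
        duration = pulse_duration + max(grid_ms) / 1000.0 + 1.0
    protocols: dict[str, StimulusProtocol] = {}
    for ch in CHANNELS:
        p = make_pulse_protocol(ch, pulse_duration, level, duration=duration)
        protocols[p.label] = p
    for dt in sorted(grid_ms):
        if dt == 0:
            p = make_asynchrony_protocol(0, "A", pulse_duration, level, duration=duration)
            protocols[p.label] = p
        else:
            for lead in CHANNELS:
                p = make_asynchrony_protocol(dt, lead, pulse_duration, level, duration=duration)
                protocols[p.label] = p
    return protocols


def valve_to_concentration(
    seq: ValveSequence,
    peak_conc: float,
    tau_rise: float = 0.020,
    tau_fall: float = 0.040,
    sampling_rate: float = 1000.0,
    t0: float = 0.0,
    pad: float = 0.0,
) -> ConcentrationTrace:
    """First-order low-pass of the binary valve state, scaled to ``peak_conc``.

    Concentration relaxes exponentially toward ``peak_conc`` with time
    constant ``tau_rise`` while the valve is open and decays toward zero
    with ``tau_fall`` while closed — a minimal model of the fast but
    non-square concentration transients a photoionization detector reports.
    ``pad`` appends closed-valve time after the sequence end so responses can
    be followed past the stimulus.
    """
    if tau_rise <= 0 or tau_fall <= 0:
        raise StimulusError("time constants must be > 0")
    if sampling_rate <= 0:
        raise StimulusError("sampling_rate must be > 0")
    n = int(round((seq.duration + pad) * sampling_rate))
    t = np.arange(n) / sampling_rate
    out = np.empty(n)
    # Piecewise-exponential solution, one closed form per inter-toggle segment.
    edges = np.concatenate(([0.0], seq.toggle_times, [seq.duration + pad]))
    c0 = 0.0
    state = seq.initial_state
    for lo, hi in zip(edges[:-1], edges[1:]):
        target = peak_conc if state else 0.0
        tau = tau_rise if state else tau_fall
        i0, i1 = np.searchsorted(t, [lo, hi], side="left")
        seg_t = t[i0:i1] - lo
        out[i0:i1] = target + (c0 - target) * np.exp(-seg_t / tau)
        c0 = target + (c0 - target) * np.exp(-(hi - lo) / tau)
        state = not state
    return ConcentrationTrace(sampling_rate=sampling_rate, values=out, t0=t0)


def compute_air_dilution(cfg: FlowConfig) -> dict[str, float]:
    """Dilution arithmetic of the two-channel olfactometer.

    Each channel releases saturated headspace at ``odorant_flow`` into
    ``dilution_air_flow`` of clean air (one or more serial stages); the
    channels then join a carrier stream.  Returns the final dimensionless
    dilution fraction per channel and the total outlet flow in L/min.
    With the published settings (3 + 297 mL/min, 1 stage, 2 channels,
    1.5 L/min carrier) the totals are 2.1 L/min and 1.43e-3.
    """
    channel_flow = cfg.odorant_flow + cfg.dilution_air_flow
    total = cfg.n_channels * channel_flow + cfg.carrier_flow
    if total <= 0:
        raise StimulusError("total flow must be > 0")
    if cfg.final_fraction_override is not None:
        fraction = cfg.final_fraction_override
    elif channel_flow == 0:
        fraction = 0.0
    else:
        per_stage = cfg.odorant_flow / channel_flow
        fraction = per_stage**cfg.n_dilution_stages * (channel_flow / total)
    return {"dilution_fraction": fraction, "total_flow": total / 1000.0}
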