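"""Spike-train metrics: causal rate estimation, response windows, and the
Victor-Purpura distance.

Firing rates are estimated by convolving spike trains with a causal alpha
kernel, k(t) = (t / tau**2) * exp(-t / tau) for t >= 0 (zero before), so the
estimated rate never rises before a spike occurs.  The default time constant
tau = 50 ms matches the standard width sigma = 50 ms used throughout the
analysis; an alternative convention (sigma as the kernel's standard
deviation, tau = sigma / sqrt(2)) is switchable.

The Victor-Purpura distance D_VP between two spike trains is the minimal
total cost of transforming one train into the other, where deleting or
inserting a spike costs 1 and shifting a spike by dt costs q * |dt|.  It is
computed exactly with the standard O(n*m) dynamic program.  q (1/s) sets the
temporal precision of the comparison: q = 0 counts only the spike-count
difference, large q makes any shift more expensive than delete+insert.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .sensillum import SpikeTrain


class MetricsError(ValueError):
    """Invalid metric parameters."""


@dataclass(frozen=True)
class KernelParams:
    """Alpha-kernel width.  ``convention``: "tau" interprets sigma as the
    kernel time constant (peak at sigma); "sd" as its standard deviation."""

    sigma: float = 0.050
    convention: str = "tau"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise MetricsError("sigma must be > 0")
        if self.convention not in ("tau", "sd"):
            raise MetricsError("convention must be 'tau' or 'sd'")

    @property
    def tau(self) -> float:
        # alpha kernel SD = tau * sqrt(2)
        return self.sigma if self.convention == "tau" else self.sigma / np.sqrt(2.0)


@dataclass(frozen=True)
class VPParams:
    """Victor-Purpura cost factor q (1/s).  Default 20/s: a 100-ms shift
    costs as much as deleting and re-inserting the spike."""

    q: float = 20.0

    def __post_init__(self) -> None:
        if self.q < 0:
            raise MetricsError("q must be >= 0")


@dataclass(frozen=True)
class RateTrace:
    """Estimated instantaneous firing rate (spikes/s) on a regular grid
    starting at ``t_start`` (s, relative to stimulus onset)."""

    sampling_rate: float
    values: np.ndarray
    t_start: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.values.size) / self.sampling_rate


def alpha_kernel(k: KernelParams = KernelParams(), sampling_rate: float = 1000.0) -> np.ndarray:
    """Discretized causal alpha kernel, renormalized to unit integral.

    Samples k(t) = (t / tau**2) * exp(-t / tau) on t = 0, dt, 2*dt, ... out
    to 10 * tau and rescales so that sum * dt == 1 exactly.
    """
    tau = k.tau
    if sampling_rate * tau < 2:
        raise MetricsError("sampling_rate too low for kernel width")
    dt = 1.0 / sampling_rate
    t = np.arange(0.0, 10.0 * tau, dt)
    kern = (t / tau**2) * np.exp(-t / tau)
    kern /= kern.sum() * dt
    return kern


def estimate_rate(
    train: SpikeTrain | np.ndarray,
    k: KernelParams = KernelParams(),
    t_start: float = 0.0,
    t_stop: float | None = None,
    sampling_rate: float = 1000.0,
) -> RateTrace:
    """Causal kernel rate estimate: a kernel is placed at each spike and the
    sum evaluated on a regular grid covering ``[t_start, t_stop)``."""
    times = train.spike_times if isinstance(train, SpikeTrain) else np.asarray(train, float)
    if t_stop is None:
        t_stop = float(times.max()) + 10 * k.tau if times.size else t_start + 1.0
    n = int(round((t_stop - t_start) * sampling_rate))
    if n <= 0:
        raise MetricsError("empty rate grid")
    counts = np.zeros(n)
    idx = np.floor((times - t_start) * sampling_rate).astype(int)
    # spikes before the grid still contribute through the kernel tail
    kern = alpha_kernel(k, sampling_rate)
    pre = int(np.clip(-idx.min(initial=0), 0, kern.size))
    counts = np.zeros(n + pre)
    valid = (idx + pre >= 0) & (idx < n)
    np.add.at(counts, idx[valid] + pre, 1.0)
    rate = fftconvolve(counts, kern)[pre : pre + n]
    rate[np.abs(rate) < 1e-9] = 0.0  # FFT round-off must not break causality
    return RateTrace(sampling_rate=sampling_rate, values=np.maximum(rate, 0.0), t_start=t_start)


def window_mean_rate(
    train: SpikeTrain | np.ndarray, window: tuple[float, float] = (0.1, 0.35)
) -> float:
    """Mean firing rate as spike count in the half-open window [a, b) divided
    by the window length (the transient-response window defaults to
    0.1-0.35 s after valve opening)."""
    a, b = window
    if b <= a:
        raise MetricsError("window must satisfy a < b")
    times = train.spike_times if isinstance(train, SpikeTrain) else np.asarray(train, float)
    n = int(np.count_nonzero((times >= a) & (times < b)))
    return n / (b - a)


def response_peak_rate(rate: RateTrace, search_window: tuple[float, float] = (0.0, 0.5)) -> float:
    """Maximum of the estimated rate within ``search_window`` (half-open)."""
    a, b = search_window
    if b <= a:
        raise MetricsError("window must satisfy a < b")
    mask = (rate.times >= a) & (rate.times < b)
    if not np.any(mask):
        raise MetricsError("search window does not overlap the rate grid")
    return float(rate.values[mask].max())


def response_onset_latency(
    rate: RateTrace,
    baseline_window: tuple[float, float] = (-0.5, 0.0),
    criterion_sd: float = 3.0,
    min_hold: float = 0.010,
) -> float | None:
    """First time after t = 0 at which the rate exceeds baseline mean +
    criterion_sd * baseline SD and stays above for at least ``min_hold`` s;
    None if the rate never does."""
    a, b = baseline_window
    if b > 0:
        raise MetricsError("baseline window must precede t = 0")
    base = rate.values[(rate.times >= a) & (rate.times < b)]
    if base.size == 0:
        raise MetricsError("baseline window does not overlap the rate grid")
    thresh = base.mean() + criterion_sd * base.std()
    post = rate.times >= 0.0
    t_post = rate.times[post]
    above = rate.values[post] > thresh
    hold = max(int(round(min_hold * rate.sampling_rate)), 1)
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= hold:
            return float(t_post[i - hold + 1])
    return None


def victor_purpura_distance(
    train1: SpikeTrain | np.ndarray,
    train2: SpikeTrain | np.ndarray,
    p: VPParams = VPParams(),
) -> float:
    """Exact Victor-Purpura spike-train distance.

    Dynamic program over spike prefixes: G[i, j] is the cheapest way to
    transform the first i spikes of train 1 into the first j spikes of
    train 2 (delete / insert cost 1, shift cost q * |dt|)."""
    t1 = train1.spike_times if isinstance(train1, SpikeTrain) else np.asarray(train1, float)
    t2 = train2.spike_times if isinstance(train2, SpikeTrain) else np.asarray(train2, float)
    n, m = t1.size, t2.size
    if n == 0 or m == 0:
        return float(n + m)
    shift_cost = p.q * np.abs(t1[:, None] - t2[None, :])
    j_idx = np.arange(m + 1, dtype=float)
    prev = j_idx.copy()
    for i in range(1, n + 1):
        # candidates without the insert-from-left term ...
        cand = np.empty(m + 1)
        cand[0] = float(i)
        cand[1:] = np.minimum(prev[1:] + 1.0, prev[:-1] + shift_cost[i - 1])
        # ... then cur[j] = min_{k<=j} cand[k] + (j - k), a running minimum
        prev = np.minimum.accumulate(cand - j_idx) + j_idx
    return float(prev[m])
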