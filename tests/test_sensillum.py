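"""Two-ORN sensillum simulator: transduction calibration, ephaptic
coupling, spiking, voltage synthesis and experiment assembly."""

import dataclasses

import numpy as np
import pytest

from sensillab.metrics import estimate_rate, response_peak_rate, window_mean_rate
from sensillab.sensillum import (
    DriveTrace,
    ORNParams,
    SensillumParams,
    SimulationError,
    ephaptic_couple,
    generate_spikes,
    simulate_experiment,
    simulate_trial,
    synthesize_trace,
    transduce,
)
from sensillab.stimuli import (
    ConcentrationTrace,
    ValveSequence,
    make_asynchrony_protocol,
    make_pulse_protocol,
    valve_to_concentration,
)


def _step_conc(level: float, duration: float = 3.0, fs: float = 1000.0) -> ConcentrationTrace:
    seq = ValveSequence(np.array([0.0]), duration, "A")
    return valve_to_concentration(seq, level, tau_rise=0.010, tau_fall=0.015, sampling_rate=fs)


class TestTransduce:
    def test_low_concentration_calibration(self):
        # step at the low level: transient near the max-rate drive, sustained
        # plateau well below — drive-level counterpart of the printed
        # 70-75 / 21-25 spikes/s bands
        drive = transduce(_step_conc(1.43e-6), ORNParams())
        assert drive.values.max() > 300.0
        assert drive.values[2000] <= 25.0

    def test_zero_concentration_baseline(self):
        conc = ConcentrationTrace(1000.0, np.zeros(1000))
        drive = transduce(conc, ORNParams())
        np.testing.assert_allclose(drive.values, ORNParams().baseline_rate)

    def test_incognate_constant_baseline(self):
        drive = transduce(_step_conc(1.43e-3), ORNParams(), cognate=False)
        np.testing.assert_allclose(drive.values, ORNParams().baseline_rate)

    def test_high_exceeds_low(self):
        lo = transduce(_step_conc(1.43e-6), ORNParams())
        hi = transduce(_step_conc(1.43e-3), ORNParams())
        assert hi.values.max() > lo.values.max()
        assert hi.values[2500] > lo.values[2500]


class TestEphapticCouple:
    def _drives(self, a_val, b_val, n=1000):
        return (
            DriveTrace(1000.0, np.full(n, float(a_val))),
            DriveTrace(1000.0, np.full(n, float(b_val))),
        )

    def test_zero_coupling_identity(self, quiet_params):
        s = dataclasses.replace(quiet_params, g_ab=0.0, g_ba=0.0)
        a, b = self._drives(100.0, 80.0)
        a2, b2 = ephaptic_couple(a, b, s)
        np.testing.assert_array_equal(a2.values, a.values)
        np.testing.assert_array_equal(b2.values, b.values)

    def test_asymmetric_suppression(self, quiet_params):
        # equal suprabaseline drives: B is suppressed more than A
        a, b = self._drives(200.0, 200.0)
        a2, b2 = ephaptic_couple(a, b, quiet_params)
        supp_a = a.values[0] - a2.values[0]
        supp_b = b.values[0] - b2.values[0]
        assert supp_b > supp_a > 0

    def test_suppression_grows_with_drive(self, quiet_params):
        a1, b1 = self._drives(150.0, 150.0)
        a2, b2 = self._drives(300.0, 300.0)
        _, b1c = ephaptic_couple(a1, b1, quiet_params)
        _, b2c = ephaptic_couple(a2, b2, quiet_params)
        assert b2.values[0] - b2c.values[0] > b1.values[0] - b1c.values[0]

    def test_rectified_at_zero(self, quiet_params):
        a, b = self._drives(500.0, 30.0)
        _, b2 = ephaptic_couple(a, b, quiet_params)
        assert np.all(b2.values >= 0.0)

    def test_subthreshold_drive_does_not_couple(self, quiet_params):
        theta = quiet_params.coupling_threshold
        base = quiet_params.orn_a.baseline_rate
        a, b = self._drives(base + theta - 1.0, 100.0)
        _, b2 = ephaptic_couple(a, b, quiet_params)
        np.testing.assert_array_equal(b2.values, b.values)

    def test_mismatched_lengths_rejected(self, quiet_params):
        a = DriveTrace(1000.0, np.zeros(10))
        b = DriveTrace(1000.0, np.zeros(11))
        with pytest.raises(SimulationError):
            ephaptic_couple(a, b, quiet_params)


class TestGenerateSpikes:
    def test_zero_drive_empty_train(self):
        train = generate_spikes(DriveTrace(1000.0, np.zeros(1000)), 0.002, 1)
        assert len(train) == 0

    def test_dead_time_rate_formula(self):
        # constant 100 sp/s with 2 ms dead time realizes 100/(1+0.2) = 83.3
        drive = DriveTrace(1000.0, np.full(100_000, 100.0))
        train = generate_spikes(drive, 0.002, 7)
        rate = len(train) / 100.0
        expected = 100.0 / 1.2
        se = np.sqrt(expected * 100) / 100.0
        assert abs(rate - expected) < 3 * se

    def test_refractory_respected(self):
        drive = DriveTrace(1000.0, np.full(20_000, 400.0))
        train = generate_spikes(drive, 0.002, 3)
        assert np.diff(train.spike_times).min() >= 0.002

    def test_deterministic_given_seed(self):
        drive = DriveTrace(1000.0, np.full(5000, 50.0))
        t1 = generate_spikes(drive, 0.002, 11)
        t2 = generate_spikes(drive, 0.002, 11)
        np.testing.assert_array_equal(t1.spike_times, t2.spike_times)


class TestSynthesizeTrace:
    def test_pure_noise_sd(self, quiet_params):
        trace = synthesize_trace({}, quiet_params, seed=1, duration=10.0)
        assert trace.voltage.std() == pytest.approx(quiet_params.noise_sd, rel=0.05)

    def test_isolated_spike_amplitude(self, quiet_params):
        from sensillab.sensillum import SpikeTrain

        train = SpikeTrain(np.array([0.5]), unit="A")
        trace = synthesize_trace({"A": train}, quiet_params, seed=2, duration=1.0)
        assert trace.voltage.max() == pytest.approx(
            quiet_params.orn_a.spike_amplitude, rel=0.15
        )

    def test_burst_amplitudes_decline(self, quiet_params):
        from sensillab.sensillum import SpikeTrain

        burst = SpikeTrain(np.arange(0.1, 0.6, 0.005), unit="A")  # 200 sp/s
        s = dataclasses.replace(quiet_params, noise_sd=0.0)
        trace = synthesize_trace({"A": burst}, s, seed=3, duration=1.0)
        v = trace.voltage
        first = v[int(0.1 * 10000) : int(0.11 * 10000)].max()
        late = v[int(0.55 * 10000) : int(0.56 * 10000)].max()
        assert late < first

    def test_ground_truth_conservation(self, quiet_params):
        drive = DriveTrace(1000.0, np.full(2000, 60.0))
        trains = {
            "A": generate_spikes(drive, 0.0015, 5, unit="A"),
            "B": generate_spikes(drive, 0.0015, 6, unit="B"),
        }
        trace = synthesize_trace(trains, quiet_params, seed=7, duration=2.0)
        assert len(trace.ground_truth) == len(trains["A"]) + len(trains["B"])
        for unit in ("A", "B"):
            truth_times = sorted(t for t, u in trace.ground_truth if u == unit)
            np.testing.assert_allclose(truth_times, np.sort(trains[unit].spike_times))


class TestSimulateExperiment:
    def test_trial_counts_and_uniqueness(self, quiet_params):
        protos = {
            p.label: p
            for p in (make_pulse_protocol("A", 0.5), make_pulse_protocol("B", 0.5))
        }
        table = simulate_experiment(protos, quiet_params, n_flies=3, n_trials=4, seed=1)
        assert len(table) == 3 * 2 * 4
        keys = {(t.fly_id, t.stimulus_id, t.trial_index) for t in table}
        assert len(keys) == len(table)

    def test_determinism(self, quiet_params):
        protos = {"A": make_pulse_protocol("A", 0.5)}
        t1 = simulate_experiment(protos, quiet_params, 2, 2, seed=9)
        t2 = simulate_experiment(protos, quiet_params, 2, 2, seed=9)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(
                a.trains["A"].spike_times, b.trains["A"].spike_times
            )

    def test_zero_jitter_flies_identical(self, quiet_params):
        # same-fly parameter draw: with jitter off, fly 0 and fly 1 differ only
        # through their spiking streams, so mean rates converge
        protos = {"A": make_pulse_protocol("A", 0.5)}
        table = simulate_experiment(protos, quiet_params, 2, 30, seed=4)
        rates = {}
        for fly in (0, 1):
            counts = [
                len(t.trains["A"]) for t in table if t.fly_id == fly
            ]
            rates[fly] = np.mean(counts)
        assert rates[0] == pytest.approx(rates[1], rel=0.15)

    def test_invalid_counts_rejected(self, quiet_params):
        with pytest.raises(SimulationError):
            simulate_experiment({"A": make_pulse_protocol("A", 0.5)}, quiet_params, 0, 1)


class TestCouplingEffects:
    def test_synchronous_mixture_suppresses_b(self, quiet_params, uncoupled_params):
        proto = make_asynchrony_protocol(0, "A", 0.5, "low")
        peaks = {"on": [], "off": []}
        for i in range(25):
            for key, params in (("on", quiet_params), ("off", uncoupled_params)):
                tr = simulate_trial(proto, params, seed=np.random.SeedSequence((20, i)))
                rate = estimate_rate(tr.trains["B"], t_start=-0.4, t_stop=0.9)
                peaks[key].append(response_peak_rate(rate, (0.0, 0.5)))
        assert np.mean(peaks["on"]) < 0.85 * np.mean(peaks["off"])

    def test_suppression_monotone_in_asynchrony(self, quiet_params, uncoupled_params):
        # mean suppression of B's peak is non-increasing in |onset asynchrony|
        from scipy.stats import spearmanr

        grid = (0, 3, 6, 12, 24, 48, 96)
        supp = []
        for dt in grid:
            on, off = [], []
            proto = make_asynchrony_protocol(dt, "A", 0.5, "low")
            for i in range(20):
                for key, params, acc in (
                    ("on", quiet_params, on),
                    ("off", uncoupled_params, off),
                ):
                    tr = simulate_trial(proto, params, seed=np.random.SeedSequence((21, dt, i)))
                    rate = estimate_rate(tr.trains["B"], t_start=-0.4, t_stop=0.9)
                    win = (dt / 1000.0, dt / 1000.0 + 0.5)
                    acc.append(response_peak_rate(rate, win))
            supp.append(np.mean(off) - np.mean(on))
        rho, _ = spearmanr(grid, supp)
        assert rho < 0

    def test_concentration_dependence_of_suppression(self, quiet_params, uncoupled_params):
        # absolute suppression of B's synchronous-mixture peak is larger at
        # the high concentration
        supp = {}
        for level in ("low", "high"):
            proto = make_asynchrony_protocol(0, "A", 0.5, level)
            on, off = [], []
            for i in range(20):
                for params, acc in ((quiet_params, on), (uncoupled_params, off)):
                    tr = simulate_trial(proto, params, seed=np.random.SeedSequence((22, i)))
                    rate = estimate_rate(tr.trains["B"], t_start=-0.4, t_stop=0.9)
                    on_ = response_peak_rate(rate, (0.0, 0.5))
                    acc.append(on_)
            supp[level] = np.mean(off) - np.mean(on)
        assert supp["high"] > supp["low"]
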