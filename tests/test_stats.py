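"""Statistical pipeline: paired tests, cognate normalization, FDR battery,
synchrony window, regression and D_VP group comparisons."""

import numpy as np
import pandas as pd
import pytest

from sensillab.sensillum import SpikeTrain, Trial, TrialTable
from sensillab.stats import (
    StatsError,
    asynchrony_test_battery,
    dvp_comparison_groups,
    fdr_adjust,
    normalize_to_cognate,
    paired_t_test,
    pooled_synchrony_regression,
    synchrony_window_width,
    utest_bonferroni,
)
from sensillab.stimuli import make_fluctuating_mixture_set


class TestPairedT:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0])
        res = paired_t_test(x, x)
        assert res.statistic == 0.0 and res.p == 1.0 and res.degenerate

    def test_constant_nonzero_difference_flagged(self):
        res = paired_t_test(np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0]))
        assert res.degenerate and res.p == 0.0

    def test_matches_closed_form(self):
        # hand-computed paired t on 5 chosen pairs
        x = np.array([10.0, 12.0, 9.0, 14.0, 11.0])
        y = np.array([8.0, 11.0, 9.5, 12.0, 10.0])
        d = x - y
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        res = paired_t_test(x, y)
        assert res.statistic == pytest.approx(t_hand, abs=1e-10)

    def test_n_below_two_rejected(self):
        with pytest.raises(StatsError):
            paired_t_test(np.array([1.0]), np.array([2.0]))


def _norm_table(values_by_stim, unit="B", n_flies=4, level="low"):
    """Build a long-format response table: value = base[fly] * factor[stim]."""
    rows = []
    rng = np.random.default_rng(0)
    for fly in range(n_flies):
        base = 50 + 10 * fly
        for stim, (dt, factor) in values_by_stim.items():
            for trial in range(3):
                noise = 1 + 0.01 * rng.standard_normal()
                rows.append(
                    {
                        "fly_id": fly,
                        "stimulus_id": stim,
                        "onset_asynchrony_ms": dt,
                        "mixture_mode": None,
                        "level": level,
                        "trial": trial,
                        "unit": unit,
                        "metric": "peak_rate",
                        "value": base * factor * noise,
                    }
                )
    return pd.DataFrame(rows)


class TestNormalizeToCognate:
    def test_cognate_alone_normalizes_to_one(self):
        table = _norm_table({"B": (None, 1.0), "A0B": (0, 0.6)})
        norm = normalize_to_cognate(table)
        cog = norm[norm["stimulus_id"] == "B"]
        per_fly = cog.groupby("fly_id")["value_norm"].mean()
        np.testing.assert_allclose(per_fly, 1.0, atol=1e-12)

    def test_half_value(self):
        table = _norm_table({"B": (None, 1.0), "A0B": (0, 0.5)})
        norm = normalize_to_cognate(table)
        mixed = norm[norm["stimulus_id"] == "A0B"]["value_norm"]
        assert mixed.mean() == pytest.approx(0.5, rel=0.02)

    def test_invariant_to_fly_rescaling(self):
        table = _norm_table({"B": (None, 1.0), "A0B": (0, 0.7)})
        scaled = table.copy()
        scaled.loc[scaled["fly_id"] == 1, "value"] *= 7.3
        n1 = normalize_to_cognate(table).sort_index()["value_norm"]
        n2 = normalize_to_cognate(scaled).sort_index()["value_norm"]
        np.testing.assert_allclose(n1, n2, rtol=1e-12)

    def test_missing_cognate_rejected(self):
        table = _norm_table({"A0B": (0, 0.6)})
        with pytest.raises(StatsError):
            normalize_to_cognate(table)


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_adjusted_not_below_raw(self, rng):
        p = rng.uniform(0, 1, 30)
        assert np.all(fdr_adjust(p) >= p)

    def test_out_of_range_rejected(self):
        with pytest.raises(StatsError):
            fdr_adjust([0.5, 1.5])


class TestBattery:
    def _suppression_table(self):
        stims = {"B": (None, 1.0), "A": (None, 1.0)}
        for dt in (0, 3, 6, 12, 24, 48, 96):
            factor = 1.0 - 0.4 * np.exp(-dt / 20.0)
            if dt == 0:
                stims["A0B"] = (0, factor)
            else:
                stims[f"A{dt}B"] = (dt, factor)
                stims[f"B{dt}A"] = (-dt, factor)
        return _norm_table(stims, n_flies=6)

    def test_suppressed_stimuli_significant(self):
        norm = normalize_to_cognate(self._suppression_table())
        battery = asynchrony_test_battery(norm, "B")
        sig = battery.set_index("stimulus_id")["significant"]
        assert sig["A0B"] and sig["A3B"] and sig["B3A"]
        assert not sig["B"]

    def test_window_width_from_battery(self):
        norm = normalize_to_cognate(self._suppression_table())
        battery = asynchrony_test_battery(norm, "B")
        window = synchrony_window_width(battery)
        a = battery[(battery.onset_asynchrony_ms.notna())]
        sig_pos = a[(a.q < 0.05) & (a.onset_asynchrony_ms > 0) & (a.mean_norm < 1)]
        sig_neg = a[(a.q < 0.05) & (a.onset_asynchrony_ms < 0) & (a.mean_norm < 1)]
        expect = sig_pos.onset_asynchrony_ms.max() + (-sig_neg.onset_asynchrony_ms).max()
        assert window["width_ms"] == expect

    def test_single_fly_rejected(self):
        table = _norm_table({"B": (None, 1.0), "A0B": (0, 0.6)}, n_flies=1)
        norm = normalize_to_cognate(table)
        with pytest.raises(StatsError):
            asynchrony_test_battery(norm, "B")


class TestSynchronyWindow:
    def _battery(self, sig_dts):
        rows = []
        for dt in (0, 3, 6, 12, 24, 48, 96):
            for sign in (1, -1):
                if dt == 0 and sign == -1:
                    continue
                rows.append(
                    {
                        "unit": "B",
                        "stimulus_id": f"{dt}x{sign}",
                        "onset_asynchrony_ms": sign * dt,
                        "mean_norm": 0.7,
                        "q": 0.01 if sign * dt in sig_dts else 0.5,
                        "significant": sign * dt in sig_dts,
                    }
                )
        return pd.DataFrame(rows)

    def test_width_arithmetic(self):
        sig = {0, 3, 6, 12, 24, 48, -3, -6, -12, -24}
        assert synchrony_window_width(self._battery(sig))["width_ms"] == 72.0

    def test_nothing_significant(self):
        out = synchrony_window_width(self._battery(set()))
        assert out["width_ms"] == 0.0 and not out["any_significant"]

    def test_only_synchronous(self):
        out = synchrony_window_width(self._battery({0}))
        assert out["width_ms"] == 0.0 and out["synchronous_significant"]


class TestRegression:
    def test_exact_linear_data(self):
        stims = {"B": (None, 1.0)}
        for dt in (3, 6, 12, 24, 48, 96):
            stims[f"A{dt}B"] = (dt, 0.5 + 0.005 * dt)
        table = _norm_table(stims, n_flies=3)
        # remove noise for exactness
        table["value"] = [
            (50 + 10 * f) * (1.0 if s == "B" else 0.5 + 0.005 * abs(dt))
            for f, s, dt in zip(
                table.fly_id, table.stimulus_id, table.onset_asynchrony_ms.fillna(0)
            )
        ]
        norm = normalize_to_cognate(table)
        res = pooled_synchrony_regression(norm, "B")
        assert res.slope == pytest.approx(0.005, rel=1e-6)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)

    def test_positive_slope_for_releasing_suppression(self):
        stims = {"B": (None, 1.0)}
        for dt in (0, 3, 6, 12, 24, 48, 96):
            label = "A0B" if dt == 0 else f"A{dt}B"
            stims[label] = (dt, 1.0 - 0.4 * np.exp(-dt / 30.0))
        norm = normalize_to_cognate(_norm_table(stims, n_flies=4))
        res = pooled_synchrony_regression(norm, "B")
        assert res.slope > 0

    def test_too_few_asynchronies_rejected(self):
        stims = {"B": (None, 1.0), "A3B": (3, 0.7), "A6B": (6, 0.8)}
        norm = normalize_to_cognate(_norm_table(stims))
        with pytest.raises(StatsError):
            pooled_synchrony_regression(norm, "B")


def _tiny_trial_table(n_flies=2, n_trials=5, deterministic=False):
    protos = make_fluctuating_mixture_set(seed_a=1, seed_b=2, level="high")
    table = TrialTable(protocols=protos)
    rng = np.random.default_rng(3)
    for fly in range(n_flies):
        for label, proto in protos.items():
            for trial in range(n_trials):
                trains = {}
                for unit in ("A", "B"):
                    if deterministic:
                        times = np.arange(0.1, 1.0, 0.1)
                    else:
                        times = np.sort(rng.uniform(0, 10, 30))
                    trains[unit] = SpikeTrain(
                        times, unit=unit, fly_id=fly, stimulus_id=label, trial_index=trial
                    )
                table.trials.append(
                    Trial(fly, label, trial, proto, trains)
                )
    return table


class TestDvpGroups:
    def test_identical_trains_zero_distance(self):
        table = _tiny_trial_table(deterministic=True)
        groups = dvp_comparison_groups(table, q=20.0, pairs=(("B", "B"),))
        assert np.all(groups["d_vp"] == 0.0)

    def test_same_stimulus_pair_count(self):
        table = _tiny_trial_table(n_flies=1, n_trials=5)
        groups = dvp_comparison_groups(table, q=20.0, pairs=(("B", "B"),))
        assert len(groups[groups.unit == "B"]) == 10  # C(5, 2)

    def test_cross_stimulus_pair_count(self):
        table = _tiny_trial_table(n_flies=1, n_trials=5)
        groups = dvp_comparison_groups(table, q=20.0, pairs=(("AB_i", "B"),))
        assert len(groups[groups.unit == "B"]) == 25  # 5 x 5

    def test_missing_stimulus_rejected(self):
        table = _tiny_trial_table(n_flies=1, n_trials=2)
        with pytest.raises(StatsError):
            dvp_comparison_groups(table, pairs=(("nope", "B"),))


class TestUTest:
    def test_identical_groups(self):
        g = {"x": np.arange(10.0), "y": np.arange(10.0)}
        res = utest_bonferroni(g, [("x", "y")])[0]
        assert res.p > 0.9

    def test_fully_separated_groups(self):
        g = {"lo": np.arange(1.0, 11.0), "hi": np.arange(11.0, 21.0)}
        res = utest_bonferroni(g, [("lo", "hi")])[0]
        # U statistic at one extreme; minimal two-sided p for n = 10 vs 10
        assert res.statistic in (0.0, 100.0)
        assert res.p < 2e-4

    def test_bonferroni_single_comparison_unchanged(self):
        g = {"x": np.arange(10.0), "y": np.arange(10.0) + 0.5}
        res = utest_bonferroni(g, [("x", "y")])[0]
        assert res.p_adjusted == pytest.approx(res.p)

    def test_bonferroni_scales_and_caps(self):
        g = {"a": np.arange(5.0), "b": np.arange(5.0) + 0.1, "c": np.arange(5.0) + 0.2}
        results = utest_bonferroni(g, [("a", "b"), ("a", "c"), ("b", "c")])
        for r in results:
            assert r.p_adjusted == pytest.approx(min(r.p * 3, 1.0))

    def test_small_group_rejected(self):
        with pytest.raises(StatsError):
            utest_bonferroni({"x": np.array([1.0, 2.0]), "y": np.arange(5.0)}, [("x", "y")])
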