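"""Statistical analyses of response tables and spike-train distances.

Implements the analyses used to quantify ephaptic inhibition:

* paired t-tests of per-fly transient rates with vs. without the incognate
  odorant (background+pulse design);
* cognate normalization and the FDR-corrected (Benjamini-Hochberg) t-test
  battery over the onset-asynchrony stimulus grid;
* per-fly and average ("pooled") regressions of normalized peak rate on
  onset synchrony;
* the synchrony-window width (range of onset asynchrony that induces
  significant inhibition);
* within-animal pairwise Victor-Purpura distance groups for fluctuating
  mixtures and their two-sided Mann-Whitney U tests with Bonferroni
  correction.

Tests aggregate to per-fly means first, so the sample size entering each
test is the number of animals, matching how single-sensillum studies report
their n.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .metrics import VPParams, victor_purpura_distance
from .sensillum import TrialTable


class StatsError(ValueError):
    """Invalid statistical input."""


@dataclass(frozen=True)
class TestResult:
    comparison: str
    statistic: float
    p: float
    p_adjusted: float
    method: str  # BH | bonferroni | none
    n: tuple[int, ...]
    degenerate: bool = False

    def __post_init__(self) -> None:
        for val in (self.p, self.p_adjusted):
            if not (np.isnan(val) or 0.0 <= val <= 1.0):
                raise StatsError("p-values must lie in [0, 1]")


@dataclass(frozen=True)
class RegressionResult:
    per_fly: pd.DataFrame  # fly_id, slope, intercept, r2, p
    slope: float
    intercept: float
    r2: float
    p: float


def paired_t_test(
    cognate_only: np.ndarray, with_incognate: np.ndarray, label: str = "paired"
) -> TestResult:
    """Two-tailed paired t-test of per-fly mean rates (cognate odorant alone
    vs. with the incognate odorant added)."""
    x = np.asarray(cognate_only, float)
    y = np.asarray(with_incognate, float)
    if x.size != y.size:
        raise StatsError("paired samples must have equal length")
    if x.size < 2:
        raise StatsError("paired t-test needs n >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return TestResult(label, 0.0, 1.0, 1.0, "none", (x.size, y.size), degenerate=True)
        return TestResult(label, np.inf, 0.0, 0.0, "none", (x.size, y.size), degenerate=True)
    t, p = sps.ttest_rel(x, y)
    return TestResult(label, float(t), float(p), float(p), "none", (x.size, y.size))


def normalize_to_cognate(
    table: pd.DataFrame,
    cognate_stimulus: dict[str, str] | None = None,
    value_col: str = "value",
) -> pd.DataFrame:
    """Divide each response by the fly's mean response to the unit's cognate
    odorant alone (per fly x unit x level).

    ``table`` is long-format with columns fly_id, stimulus_id, unit, level,
    and ``value_col``.  ``cognate_stimulus`` maps unit -> stimulus label of
    the cognate-alone stimulus (default {"A": "A", "B": "B"}).
    """
    if cognate_stimulus is None:
        cognate_stimulus = {"A": "A", "B": "B"}
    out = table.copy()
    out["value_norm"] = np.nan
    for (fly, unit, level), idx in out.groupby(["fly_id", "unit", "level"]).groups.items():
        cog = out.loc[idx]
        ref = cog[cog["stimulus_id"] == cognate_stimulus[unit]][value_col]
        if ref.empty:
            raise StatsError(f"no cognate-alone trials for fly {fly}, unit {unit}, level {level}")
        ref_mean = ref.mean()
        if ref_mean == 0:
            raise StatsError(f"zero cognate mean for fly {fly}, unit {unit}, level {level}")
        out.loc[idx, "value_norm"] = out.loc[idx, value_col] / ref_mean
    return out


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, float)
    if np.any((p < 0) | (p > 1)):
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def asynchrony_test_battery(
    normalized: pd.DataFrame,
    unit: str,
    cognate_stimulus: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-stimulus two-tailed t-tests of normalized responses vs. the
    cognate-alone response, BH-corrected within the unit's battery.

    Per-fly mean normalized responses are compared with the per-fly mean
    normalized cognate-alone response (identically 1 by construction), so
    each test is a paired t-test with n = number of flies.  Returns one row
    per stimulus with t, p, q (BH-adjusted) and the per-fly mean.
    """
    if cognate_stimulus is None:
        cognate_stimulus = unit
    sub = normalized[normalized["unit"] == unit]
    per_fly = (
        sub.groupby(["stimulus_id", "fly_id"], sort=False)["value_norm"].mean().reset_index()
    )
    rows = []
    for stim, grp in per_fly.groupby("stimulus_id", sort=False):
        vals = grp["value_norm"].to_numpy()
        if vals.size < 2:
            raise StatsError(f"battery needs >= 2 flies per stimulus (got {vals.size} for {stim})")
        d = vals - 1.0
        if np.allclose(d.std(ddof=1), 0.0):
            t, p, degen = (0.0, 1.0, True) if np.allclose(d, 0) else (np.inf, 0.0, True)
        else:
            t, p = sps.ttest_1samp(vals, 1.0)
            degen = False
        proto_rows = sub[sub["stimulus_id"] == stim]
        dt = proto_rows["onset_asynchrony_ms"].iloc[0] if len(proto_rows) else np.nan
        rows.append(
            {
                "unit": unit,
                "stimulus_id": stim,
                "onset_asynchrony_ms": dt,
                "mean_norm": float(vals.mean()),
                "t": float(t),
                "p": float(p),
                "n_flies": int(vals.size),
                "degenerate": degen,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = fdr_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out


def synchrony_window_width(battery: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Width (ms) of the synchrony window of inhibition.

    From a battery of asynchrony-stimulus tests: the largest significant
    |onset asynchrony| with A leading plus the largest with B leading,
    counting only stimuli whose mean normalized response is suppressed
    (< 1).  0 if only the synchronous stimulus (or nothing) is significant.
    """
    mix = battery.dropna(subset=["onset_asynchrony_ms"])
    sig = mix[(mix["q"] < alpha) & (mix["mean_norm"] < 1.0)]
    a_side = sig[sig["onset_asynchrony_ms"] > 0]["onset_asynchrony_ms"]
    b_side = -sig[sig["onset_asynchrony_ms"] < 0]["onset_asynchrony_ms"]
    sync_sig = bool((sig["onset_asynchrony_ms"] == 0).any())
    width = float(a_side.max() if len(a_side) else 0.0) + float(
        b_side.max() if len(b_side) else 0.0
    )
    return {
        "width_ms": width,
        "any_significant": sync_sig or len(sig) > 0,
        "synchronous_significant": sync_sig,
        "a_leading_max_ms": float(a_side.max()) if len(a_side) else 0.0,
        "b_leading_max_ms": float(b_side.max()) if len(b_side) else 0.0,
    }


def pooled_synchrony_regression(normalized: pd.DataFrame, unit: str) -> RegressionResult:
    """Regress normalized peak rate on onset asynchrony, pooling the two
    pulse orders: x = |onset asynchrony| (ms), y = normalized peak rate.
    Inhibition that grows with synchrony releases with asynchrony, so a
    positive slope indicates synchrony-dependent inhibition.  Returns
    per-fly ordinary least squares fits and the average regression over
    all points."""
    sub = normalized[
        (normalized["unit"] == unit) & normalized["onset_asynchrony_ms"].notna()
    ].copy()
    if sub.empty:
        raise StatsError("no asynchrony-pair rows for regression")
    sub["x"] = sub["onset_asynchrony_ms"].abs()
    rows = []
    for fly, grp in sub.groupby("fly_id"):
        if grp["x"].nunique() < 3:
            raise StatsError(f"fly {fly} has fewer than 3 distinct asynchronies")
        res = sps.linregress(grp["x"], grp["value_norm"])
        rows.append(
            {
                "fly_id": fly,
                "slope": res.slope,
                "intercept": res.intercept,
                "r2": res.rvalue**2,
                "p": res.pvalue,
            }
        )
    allfit = sps.linregress(sub["x"], sub["value_norm"])
    return RegressionResult(
        per_fly=pd.DataFrame(rows),
        slope=float(allfit.slope),
        intercept=float(allfit.intercept),
        r2=float(allfit.rvalue**2),
        p=float(allfit.pvalue),
    )


#: D_VP comparisons quantifying mixture effects on response reproducibility.
DEFAULT_DVP_PAIRS = (
    ("A", "A"),
    ("B", "B"),
    ("AB_i", "AB_i"),
    ("AB_i", "A"),
    ("AB_i", "B"),
    ("AB_A", "A"),
    ("AB_B", "B"),
)


def dvp_comparison_groups(
    trials: TrialTable,
    q: float = 20.0,
    pairs: tuple[tuple[str, str], ...] = DEFAULT_DVP_PAIRS,
    units: tuple[str, ...] = ("A", "B"),
    window: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Within-animal pairwise Victor-Purpura distances for stimulus pairs.

    For a pair (X, Y): every cross-trial distance between one response to X
    and one to Y within the same fly (all unordered trial pairs when X = Y,
    excluding self-pairs), computed per unit and pooled across flies.
    Returns long-format rows (unit, pair, fly_id, trial_i, trial_j, d_vp).
    """
    vp = VPParams(q=q)
    by_key: dict[tuple[int, str, str], list[np.ndarray]] = {}
    for tr in trials:
        for unit, train in tr.trains.items():
            st = train.spike_times
            if window is not None:
                st = st[(st >= window[0]) & (st < window[1])]
            by_key.setdefault((tr.fly_id, tr.stimulus_id, unit), []).append(st)
    flies = sorted({k[0] for k in by_key})
    stims = {k[1] for k in by_key}
    rows = []
    for x, y in pairs:
        if x not in stims or y not in stims:
            raise StatsError(f"missing stimulus {x!r} or {y!r} in trial table")
        for fly in flies:
            for unit in units:
                tx = by_key.get((fly, x, unit), [])
                ty = by_key.get((fly, y, unit), [])
                if x == y:
                    combos = itertools.combinations(range(len(tx)), 2)
                    pairs_idx = [(i, j) for i, j in combos]
                else:
                    pairs_idx = [(i, j) for i in range(len(tx)) for j in range(len(ty))]
                for i, j in pairs_idx:
                    rows.append(
                        {
                            "unit": unit,
                            "pair": f"({x}, {y})",
                            "stim_i": x,
                            "stim_j": y,
                            "fly_id": fly,
                            "trial_i": i,
                            "trial_j": j,
                            "q": q,
                            "d_vp": victor_purpura_distance(tx[i], ty[j], vp),
                        }
                    )
    return pd.DataFrame(rows)


def utest_bonferroni(
    groups: dict[str, np.ndarray],
    comparisons: list[tuple[str, str]],
) -> list[TestResult]:
    """Two-sided Mann-Whitney U tests between named groups, Bonferroni-
    corrected over the listed comparisons (p x m, capped at 1)."""
    m = len(comparisons)
    results = []
    for ga, gb in comparisons:
        xa, xb = np.asarray(groups[ga], float), np.asarray(groups[gb], float)
        if xa.size < 3 or xb.size < 3:
            raise StatsError(f"U test needs n >= 3 per group ({ga} vs {gb})")
        u, p = sps.mannwhitneyu(xa, xb, alternative="two-sided")
        results.append(
            TestResult(
                comparison=f"{ga} vs {gb}",
                statistic=float(u),
                p=float(p),
                p_adjusted=float(min(p * m, 1.0)),
                method="bonferroni",
                n=(xa.size, xb.size),
            )
        )
    return results
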