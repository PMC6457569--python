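"""Temperature imputation, correlations, pair screening, naive summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from edna_occupancy.field import (
    PairComparison,
    correlation_time_temp,
    design_counts,
    exclude_pairs,
    impute_temperature,
    naive_summary,
    pair_table,
    paired_concentration_test,
)


def make_samples(times, temps, imputed=None):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(times))],
            "time_min": times,
            "water_temp_c": temps,
            "temp_imputed": [False] * len(times) if imputed is None else imputed,
        }
    )


class TestImputation:
    def test_no_missing_is_identity(self):
        df = make_samples(np.arange(500, 520), 20.0 + np.arange(20) * 0.1)
        out = impute_temperature(df)
        pd.testing.assert_frame_equal(out, df)

    def test_exact_line_recovered(self):
        times = np.array([500, 520, 540, 560, 580, 620, 640, 660, 680, 700, 600])
        temps = 20.0 + 0.01 * times
        temps[-1] = np.nan
        out = impute_temperature(make_samples(times, temps))
        assert out["water_temp_c"].iloc[-1] == pytest.approx(26.0, abs=1e-9)
        assert out["temp_imputed"].iloc[-1]
        assert not out["temp_imputed"].iloc[:-1].any()

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            impute_temperature(make_samples([1, 2, 3], [np.nan] * 3))


class TestCorrelation:
    def test_perfect_line(self):
        df = make_samples(np.arange(500, 540, 2), 10 + 0.5 * np.arange(500, 540, 2))
        r, t, dof, p = correlation_time_temp(df)
        assert r == pytest.approx(1.0)
        assert np.isinf(t) and p == 0.0

    def test_df_contract_and_imputed_exclusion(self):
        rng = np.random.default_rng(0)
        times = rng.uniform(480, 780, 240)
        temps = 15 + 0.01 * times + rng.normal(0, 2, 240)
        imputed = [True] * 5 + [False] * 235
        df = make_samples(times, temps, imputed)
        _, _, dof, _ = correlation_time_temp(df, exclude_imputed=True)
        assert dof == 233
        _, _, dof_all, _ = correlation_time_temp(df, exclude_imputed=False)
        assert dof_all == 238

    def test_hand_computed_five_points(self):
        df = make_samples([0, 1, 2, 3, 4], [1, 3, 2, 5, 4])
        r, t, dof, p = correlation_time_temp(df)
        assert r == pytest.approx(0.8, abs=1e-12)
        assert t == pytest.approx(2.3094010767585034, abs=1e-12)
        assert dof == 3

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            times = rng.uniform(480, 780, 50)
            temps = 20 + 0.01 * times + rng.normal(0, 1, 50)
            r, t, dof, p = correlation_time_temp(make_samples(times, temps))
            ref = stats.pearsonr(times, temps)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation_time_temp(make_samples([1, 2, 3], [5.0, 5.0, 5.0]))


def pair_frame(colony_temps, control_temps, colony_conc=0.0, control_conc=0.0, pid="P01"):
    rows = []
    for i, tp in enumerate(colony_temps):
        rows.append(dict(pair_id=pid, island_type="colony", site_id=f"{pid}C", sample_id=f"{pid}c{i}", water_temp_c=tp, concentration=colony_conc))
    for i, tp in enumerate(control_temps):
        rows.append(dict(pair_id=pid, island_type="control", site_id=f"{pid}T", sample_id=f"{pid}t{i}", water_temp_c=tp, concentration=control_conc))
    return pd.DataFrame(rows)


class TestPairScreen:
    def test_boundary_is_excluded_below_is_kept(self):
        at = pair_table(pair_frame([20.0, 21.0, 22.0], [29.0, 29.0, 29.0]))[0]
        assert at.temp_median_diff == pytest.approx(8.0) and at.excluded
        below = pair_table(pair_frame([20.0, 21.1, 22.0], [29.0, 29.0, 29.0]))[0]
        assert below.temp_median_diff == pytest.approx(7.9) and not below.excluded

    def test_median_is_order_free(self):
        base = pair_frame([20.0, 25.0, 22.0], [28.0, 26.0, 30.0])
        shuffled = base.sample(frac=1.0, random_state=1)
        assert pair_table(base)[0] == pair_table(shuffled)[0]

    def test_missing_side_rejected(self):
        df = pair_frame([20.0], [25.0])
        with pytest.raises(ValueError, match="missing one side"):
            pair_table(df[df.island_type == "colony"])

    def test_partition(self):
        pairs = [
            PairComparison("P01", 1, 0, 0.0, False),
            PairComparison("P02", 1, 0, 9.0, True),
        ]
        kept, dropped = exclude_pairs(pairs)
        assert [p.pair_id for p in kept] == ["P01"]
        assert [p.pair_id for p in dropped] == ["P02"]


class TestPairedTest:
    def test_identical_totals(self):
        pairs = [PairComparison(f"P{i}", 2.0, 2.0, 0.0, False) for i in range(5)]
        mean, sd, t, dof, p = paired_concentration_test(pairs)
        assert (mean, sd, t, p) == (0.0, 0.0, 0.0, 1.0) and dof == 4

    def test_hand_arithmetic(self):
        pairs = [PairComparison(f"P{i}", d, 0.0, 0.0, False) for i, d in enumerate([1.0, 2.0, 3.0])]
        mean, sd, t, dof, p = paired_concentration_test(pairs)
        assert (mean, sd, dof) == (2.0, 1.0, 2)
        assert t == pytest.approx(2 * np.sqrt(3), abs=1e-12)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            c1 = rng.lognormal(0, 1, 12)
            c2 = rng.lognormal(0, 1, 12)
            pairs = [PairComparison(f"P{i}", a, b, 0.0, False) for i, (a, b) in enumerate(zip(c1, c2))]
            mean, sd, t, dof, p = paired_concentration_test(pairs)
            ref = stats.ttest_rel(c1, c2)
            assert t == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)
            assert dof == 11

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            paired_concentration_test([PairComparison("P", 1, 0, 0, False)])


class TestNaiveSummary:
    def _frame(self):
        rows = []
        concs = {("colony", 0): [1.5, 0.0], ("colony", 1): [0.0, 0.0], ("control", 0): [0.4, 0.0], ("control", 1): [0.0, 0.0]}
        for (typ, s), cs in concs.items():
            for i, c in enumerate(cs):
                rows.append(dict(island_type=typ, site_id=f"{typ}{s}", sample_id=f"{typ}{s}-{i}", concentration=c))
        return pd.DataFrame(rows)

    def test_counts_and_percent_recount(self):
        t = naive_summary(self._frame())
        assert t.loc["colony", "positive_samples"] == 1
        assert t.loc["colony", "pct_positive"] == 25.0
        assert t.loc["colony", "positive_sites"] == 1 and t.loc["colony", "total_sites"] == 2
        assert t.loc["colony", "mean_site_total"] == pytest.approx(0.75)
        assert t.loc["control", "min_positive"] == 0.4

    def test_site_total_conservation(self):
        df = self._frame()
        t = naive_summary(df)
        total_from_sites = (t["mean_site_total"] * t["total_sites"]).sum()
        assert total_from_sites == pytest.approx(df["concentration"].sum())

    def test_all_zero_stratum(self):
        df = self._frame()
        df["concentration"] = 0.0
        t = naive_summary(df)
        assert t.loc["colony", "pct_positive"] == 0.0
        assert np.isnan(t.loc["colony", "min_positive"])

    def test_empty_stratum_rejected(self):
        df = self._frame()
        with pytest.raises(ValueError):
            naive_summary(df[df.island_type == "colony"])


class TestDesignCounts:
    def test_all_morning(self):
        df = pair_frame([21.0, 22.0], [23.0, 24.0])
        df["time_min"] = 600
        out = design_counts(df)
        assert out["colony_pct_before"] == 100.0 and out["control_pct_before"] == 100.0
        assert out["in_temp_range"] == 4

    def test_empty_range_query(self):
        df = pair_frame([10.0], [11.0])
        df["time_min"] = 700
        out = design_counts(df, temp_range=(50.0, 60.0))
        assert out["in_temp_range"] == 0
        assert out["colony_before_cutoff"] == 0
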