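"""Group summaries, Welch tests, OLS and SPM-sediment pairing."""

import math

import numpy as np
import pytest

from gdgtproxy import (
    Dataset,
    SampleRecord,
    gene_ratio,
    group_summary,
    ols_regression,
    paired_station_correlation,
    welch_t_test,
)


def normal_equation_fit(x, y):
    """Independent OLS oracle: closed-form normal equations + slope t-test."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    syy = np.sum((y - y.mean()) ** 2)
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    r2 = sxy**2 / (sxx * syy) if syy > 0 else 0.0
    resid = y - intercept - slope * x
    se = math.sqrt(np.sum(resid**2) / (n - 2) / sxx)
    from scipy.stats import t as tdist

    tval = slope / se if se > 0 else math.inf
    p = 2 * tdist.sf(abs(tval), n - 2)
    return slope, intercept, r2, p


class TestGeneRatio:
    def test_table_values(self, table1):
        assert gene_ratio(table1["M_bott"]) == pytest.approx(1.6e9 / 5.1e9, abs=1e-9)
        assert gene_ratio(table1["R1_bott"]) == pytest.approx(1.2e3 / 3.6e8, rel=1e-9)

    def test_equal_abundances_give_unity(self):
        r = SampleRecord(sample_id="x", archaea_16s=2e8, mgii_16s=2e8)
        assert gene_ratio(r) == 1.0

    def test_absent_abundance_is_undefined(self, table1):
        assert math.isnan(gene_ratio(table1["R2_sur"]))

    def test_ratio_above_one_warns(self):
        r = SampleRecord(sample_id="x", archaea_16s=1e8, mgii_16s=2e8)
        with pytest.warns(UserWarning, match="exceeds"):
            assert gene_ratio(r) == 2.0


class TestGroupSummary:
    def test_mixing_cl_ring_index(self, table1):
        (gs,) = [
            g for g in group_summary(table1, "water_type", "ri2", pool="CL")
            if g.group_key[0] == "mixing"
        ]
        assert gs.n == 6
        assert round(gs.mean, 2) == 0.39
        assert round(gs.sd, 2) == 0.08

    def test_river_mgii_copies(self, table1):
        (gs,) = [
            g for g in group_summary(table1, "water_type", "mgii_16s")
            if g.group_key[0] == "river"
        ]
        assert gs.n == 2  # only R1_sur / R1_bott were assayed
        assert gs.mean == pytest.approx(1.506e5, rel=1e-6)

    def test_single_record_group_has_no_sd(self):
        ds = Dataset([
            SampleRecord(sample_id="a", water_type="river", mgii_16s=5.0, archaea_16s=10.0),
            SampleRecord(sample_id="b", water_type="sea", mgii_16s=1.0, archaea_16s=10.0),
            SampleRecord(sample_id="c", water_type="sea", mgii_16s=3.0, archaea_16s=10.0),
        ])
        by_group = {g.group_key[0]: g for g in group_summary(ds, "water_type", "gene_ratio")}
        assert by_group["river"].n == 1
        assert math.isnan(by_group["river"].sd)
        assert by_group["river"].mean == 0.5
        assert by_group["sea"].sd_pop == pytest.approx(0.1)

    def test_no_defined_values_warns_and_empties(self, table1):
        sediments = table1.subset(lambda r: r.water_type == "sediment")
        with pytest.warns(UserWarning, match="no defined values"):
            assert group_summary(sediments, "water_type", "gene_ratio") == []

    def test_order_invariance(self, table1):
        reversed_ds = Dataset(list(table1)[::-1])
        a = group_summary(table1, "water_type", "ri2", pool="phospho_IPL")
        b = group_summary(reversed_ds, "water_type", "ri2", pool="phospho_IPL")
        assert [(g.group_key, g.n) for g in a] == [(g.group_key, g.n) for g in b]
        for ga, gb in zip(a, b):
            assert ga.mean == pytest.approx(gb.mean, rel=1e-12)


class TestWelch:
    def test_identical_groups(self):
        res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_zero_variance_difference(self):
        res = welch_t_test([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert res.p_value == 0.0 and res.statistic == -math.inf

    def test_symmetry(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 5.0, 9.0, 2.0]
        assert welch_t_test(a, b).p_value == pytest.approx(
            welch_t_test(b, a).p_value, rel=1e-12
        )

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])

    def test_mixing_vs_sea_gene_ratio(self, table1):
        mix = [gene_ratio(r) for r in table1 if r.water_type == "mixing"]
        sea = [gene_ratio(r) for r in table1
               if r.water_type == "sea" and not math.isnan(gene_ratio(r))]
        assert len(mix) == 6 and len(sea) == 4
        res = welch_t_test(mix, sea)
        assert res.statistic > 0
        assert res.p_value < 0.05


class TestOLS:
    def test_perfect_line(self):
        x = np.arange(5.0)
        res = ols_regression(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0, abs=1e-12)
        assert res.intercept == pytest.approx(1.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_residuals_give_zero_slope(self):
        res = ols_regression([0.0, 1.0, 2.0], [0.0, 1.0, 0.0])
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ols_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            ols_regression([1.0, 2.0], [1.0, 2.0])

    def test_nan_pairs_dropped_pairwise(self):
        x = [0.0, 1.0, 2.0, 3.0, math.nan]
        y = [1.0, 3.0, math.nan, 7.0, 9.0]
        res = ols_regression(x, y)
        assert res.n == 3
        assert res.slope == pytest.approx(2.0, abs=1e-12)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = rng.integers(3, 12)
            x = rng.normal(size=n)
            if np.allclose(x, x[0]):
                continue
            y = rng.normal(size=n)
            res = ols_regression(x, y)
            slope, intercept, r2, p = normal_equation_fit(x, y)
            assert res.slope == pytest.approx(slope, rel=1e-9, abs=1e-9)
            assert res.intercept == pytest.approx(intercept, rel=1e-9, abs=1e-9)
            assert res.r_squared == pytest.approx(r2, rel=1e-9, abs=1e-9)
            assert res.p_value == pytest.approx(p, rel=1e-9, abs=1e-12)

    def test_r_squared_equals_squared_pearson(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = ols_regression(x, y)
        assert res.r_squared == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-12)


class TestPairedStationCorrelation:
    def test_fixture_station_means(self, table1):
        res, strategy = paired_station_correlation(
            table1, variable="tex86", pool="CL", pairing="station-mean"
        )
        assert strategy == "station-mean"
        assert res.n == 8  # every station has a sediment sample
        assert 0.0 <= res.r_squared <= 1.0

    def test_identical_values_give_perfect_fit(self):
        records = []
        for i, v in enumerate([0.4, 0.5, 0.6, 0.7]):
            records.append(SampleRecord(
                sample_id=f"spm{i}", station=f"st{i}", water_type="sea",
                indices={"CL": _ix(v)}))
            records.append(SampleRecord(
                sample_id=f"sed{i}", station=f"st{i}", water_type="sediment",
                indices={"CL": _ix(v)}))
        res, _ = paired_station_correlation(Dataset(records), "tex86", "CL")
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_stations_rejected(self):
        records = []
        for i, v in enumerate([0.4, 0.5]):
            records.append(SampleRecord(
                sample_id=f"spm{i}", station=f"st{i}", water_type="sea",
                indices={"CL": _ix(v)}))
            records.append(SampleRecord(
                sample_id=f"sed{i}", station=f"st{i}", water_type="sediment",
                indices={"CL": _ix(v)}))
        with pytest.raises(ValueError):
            paired_station_correlation(Dataset(records), "tex86", "CL")

    def test_unknown_strategy_rejected(self, table1):
        with pytest.raises(ValueError):
            paired_station_correlation(table1, pairing="nearest")


def _ix(tex):
    from gdgtproxy import IndexSet

    return IndexSet(tex86=tex)
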