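"""Univariate penetrance regression: oracles, identities, calibration."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

import fampen as fp
from fampen import DegenerateDataError, PenetranceRegressor, TraitPairs
from fampen.reference import univariate_summary

from conftest import single_trait_config


def _random_pairs(rng, n, spec):
    x = rng.normal(100, 10, n)
    y = rng.normal(80, 12, n) + 0.5 * (x - 100)
    return TraitPairs(trait=spec, proband=y, family=x)


class TestCorrelation:
    def test_perfect_collinearity(self, fsiq_spec):
        x = np.arange(10, dtype=float)
        pairs = TraitPairs(trait=fsiq_spec, proband=2 * x + 1, family=x)
        r, p = fp.trait_correlation(pairs)
        assert r == pytest.approx(1.0)
        assert p < 1e-30

    def test_brute_force_formula(self, fsiq_spec):
        rng = np.random.default_rng(101)
        x, y = rng.normal(size=10), rng.normal(size=10)
        pairs = TraitPairs(trait=fsiq_spec, proband=y, family=x)
        r, _ = fp.trait_correlation(pairs)
        # direct covariance / (sd * sd) oracle
        r_oracle = (((x - x.mean()) * (y - y.mean())).mean()
                    / (x.std(ddof=0) * y.std(ddof=0)))
        assert abs(r - r_oracle) < 1e-12

    def test_published_fsiq_correlation_is_highly_significant(self):
        assert fp.correlation_pvalue(0.63, 57) <= 1e-4

    def test_zero_variance_degenerate(self, fsiq_spec):
        pairs = TraitPairs(trait=fsiq_spec, proband=[1.0, 2.0, 3.0],
                           family=[5.0, 5.0, 5.0])
        with pytest.raises(DegenerateDataError):
            fp.trait_correlation(pairs)


class TestOffsetModel:
    def test_identity_data(self, fsiq_spec):
        x = np.array([90.0, 100.0, 105.0, 110.0, 120.0])
        pairs = TraitPairs(trait=fsiq_spec, proband=x.copy(), family=x)
        res = fp.fit_offset_model(pairs)
        assert res.offset == pytest.approx(0.0, abs=1e-12)
        assert res.slope == pytest.approx(1.0, abs=1e-12)
        assert res.p_slope_vs1 == 1.0

    def test_matches_statsmodels(self, fsiq_spec):
        rng = np.random.default_rng(7)
        pairs = _random_pairs(rng, 40, fsiq_spec)
        res = fp.fit_offset_model(pairs)
        xc = pairs.family - pairs.family.mean()
        yc = pairs.proband - pairs.family.mean()
        ols = sm.OLS(yc, sm.add_constant(xc)).fit()
        assert res.offset == pytest.approx(ols.params[0], abs=1e-10)
        assert res.slope == pytest.approx(ols.params[1], abs=1e-10)
        assert res.slope_se == pytest.approx(ols.bse[1], abs=1e-10)
        assert res.p_slope_vs0 == pytest.approx(ols.pvalues[1], abs=1e-10)
        assert res.adj_r2 == pytest.approx(ols.rsquared_adj, abs=1e-10)
        assert res.p_offset == pytest.approx(ols.pvalues[0], abs=1e-10)

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=50)
    def test_centering_identity(self, fsiq_spec, seed):
        """The fitted offset equals mean(proband) - mean(family score)."""
        rng = np.random.default_rng(seed)
        pairs = _random_pairs(rng, int(rng.integers(4, 60)), fsiq_spec)
        res = fp.fit_offset_model(pairs)
        assert abs(res.offset - (pairs.proband.mean() - pairs.family.mean())) < 1e-9

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=50)
    def test_slope_vs0_p_equals_pearson_p(self, fsiq_spec, seed):
        rng = np.random.default_rng(seed)
        pairs = _random_pairs(rng, 30, fsiq_spec)
        res = fp.fit_offset_model(pairs)
        _, p_r = fp.trait_correlation(pairs)
        assert abs(res.p_slope_vs0 - p_r) < 1e-9
        assert abs(res.p_slope_vs0 - res.p_r) < 1e-9

    def test_cohen_d_identity_on_published_offsets(self):
        """offset / normative SD reproduces every published bracketed d."""
        uni = univariate_summary()
        specs = {s.name: s for s in fp.default_battery()}
        for trait, row in uni.iterrows():
            d = row["offset"] / specs[trait].norm_sd
            assert abs(d - row["cohen_d"]) <= 0.005 + 1e-9, trait

    def test_adjusted_r2_worked_examples(self):
        uni = univariate_summary()
        for trait in ("fsiq", "vocabulary", "matrix_reasoning"):
            row = uni.loc[trait]
            adj = fp.adjusted_r2(row["r"] ** 2, int(row["proband_n"]))
            assert abs(adj - row["adj_r2"]) <= 0.005, trait

    def test_too_few_pairs(self, fsiq_spec):
        pairs = TraitPairs(trait=fsiq_spec, proband=[1.0, 2.0, 3.0],
                           family=[1.0, 2.0, 4.0])
        with pytest.raises(DegenerateDataError):
            fp.fit_offset_model(pairs)

    def test_estimator_predict_passes_through_mean_point(self, fsiq_spec):
        rng = np.random.default_rng(21)
        pairs = _random_pairs(rng, 25, fsiq_spec)
        est = PenetranceRegressor(norm_sd=15).fit(pairs.family, pairs.proband)
        pred = est.predict([pairs.family.mean()])
        assert pred[0] == pytest.approx(pairs.proband.mean(), abs=1e-9)

    def test_get_set_params_round_trip(self):
        est = PenetranceRegressor(norm_sd=15)
        assert PenetranceRegressor(**est.get_params()).norm_sd == 15


class TestCalibration:
    def test_slope_vs1_type_I_error(self, fsiq_spec):
        """Null slope-vs-1 test rejects at ~5% (2,000 replicates)."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep, n = 2000, 58
        for _ in range(n_rep):
            x = rng.normal(100, 10, n)
            y = x + rng.normal(0, 10, n)  # true slope exactly 1
            res = PenetranceRegressor().fit(x, y)
            rejections += res.p_slope_vs1_ < 0.05
        rate = rejections / n_rep
        assert abs(rate - 0.05) < 0.02  # ~4 MC SEs at 2,000 replicates

    def test_offset_estimator_unbiased(self, fsiq_spec):
        """Mean offset bias across generator replicates is within 3 SE of 0."""
        true_offset = -20.15
        offsets = []
        for rep in range(300):
            cfg = single_trait_config(
                fsiq_spec, n_families=58, seed=50_000 + rep, family_mean=107.0,
                between=8.0, within=7.0, offset=true_offset, slope=0.94,
                noise=11.0, availability={"mother": 57 / 58, "father": 34 / 58,
                                          "sibling": 24 / 58})
            table, _ = fp.generate_cohort(cfg)
            offsets.append(fp.fit_offset_model(fp.make_pairs(table, "fsiq")).offset)
        offsets = np.asarray(offsets)
        se = offsets.std(ddof=1) / np.sqrt(len(offsets))
        assert abs(offsets.mean() - true_offset) < 3 * se


class TestTable:
    def test_full_battery_gives_twelve_rows(self, xyy_table):
        results, skips = fp.penetrance_table(xyy_table)
        assert len(results) == 12 and not skips
        frame = fp.results_frame(results)
        assert set(frame["trait"]) == set(xyy_table.trait_names)
        # every row satisfies the Cohen's d identity
        for res in results:
            spec = xyy_table.spec(res.trait)
            assert abs(abs(res.cohen_d) - abs(res.offset) / spec.norm_sd) < 1e-12

    def test_degenerate_trait_reported_as_skip(self, xyy_table):
        data = xyy_table.data.copy()
        data["srs_total"] = 50.0  # constant -> zero variance everywhere
        table = fp.FamilyTable.from_frame(data, xyy_table.trait_specs.values())
        results, skips = fp.penetrance_table(table)
        assert len(results) == 11
        assert [s.trait for s in skips] == ["srs_total"]

    def test_bonferroni_rule(self):
        assert fp.bonferroni_adjust([0.004, 0.01, 0.0], m=12) == [True, False, True]

    def test_large_n_offsets_recover_configured_values(self):
        """Fitted offsets on a large preset cohort match the configured ones."""
        cfg = fp.xyy_like_config(n_families=4000, seed=77)
        table, truth = fp.generate_cohort(cfg)
        results, _ = fp.penetrance_table(table)
        for res in results:
            true = truth.offsets[res.trait]
            # conservative CI: 4 * analytic SE of a mean difference
            assert abs(res.offset - true) < 1.5, res.trait
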