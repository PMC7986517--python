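"""Cross-trait / covariate models and the nested partial-F comparison."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.stats.anova import anova_lm

import fampen as fp
from fampen import DegenerateDataError
from fampen.multivariate import _fit_ols, compare_models, design_frame


def _noise_cohort(seed, n_families=58, srs_beta=0.0):
    """Two-trait cohort with full covariates and configurable FSIQ->SRS coupling."""
    specs = [s for s in fp.default_battery() if s.name in ("fsiq", "srs_total")]
    cfg = fp.SimConfig(
        n_families=n_families,
        trait_specs=specs,
        between_family_sd={"fsiq": 10.0, "srs_total": 5.0},
        within_family_sd={"fsiq": 5.0, "srs_total": 4.0},
        proband_offset={"fsiq": -20.0, "srs_total": 17.0},
        proband_slope={"fsiq": 0.9, "srs_total": 0.0},
        proband_noise_sd={"fsiq": 10.0, "srs_total": 10.0},
        cross_trait_beta=({("fsiq", "srs_total"): srs_beta} if srs_beta else {}),
        availability_probs={"mother": 1.0, "father": 34 / 58, "sibling": 24 / 58},
        seed=seed,
    )
    return fp.generate_cohort(cfg)[0]


class TestModelFits:
    def test_hand_built_normal_equations_oracle(self):
        """Model 1 coefficients equal the brute-force normal-equations solution."""
        rows = []
        rng = np.random.default_rng(3)
        for i in range(8):
            fam = f"F{i}"
            fsiq_fam = 100 + rng.normal(0, 10)
            srs_fam = 50 + rng.normal(0, 5)
            rows += [
                {"family_id": fam, "role": "proband",
                 "fsiq": fsiq_fam - 20 + rng.normal(), "srs_total": 60 + rng.normal()},
                {"family_id": fam, "role": "mother",
                 "fsiq": fsiq_fam, "srs_total": srs_fam},
            ]
        specs = [s for s in fp.default_battery() if s.name in ("fsiq", "srs_total")]
        table = fp.FamilyTable.from_frame(pd.DataFrame(rows), specs)
        fit = fp.fit_model1(table, "srs_total")
        frame = design_frame(table, "srs_total").dropna(
            subset=["proband_trait", "family_trait", "family_fsiq"])
        X = np.column_stack([np.ones(len(frame)), frame["family_trait"],
                             frame["family_fsiq"]])
        beta = np.linalg.solve(X.T @ X, X.T @ frame["proband_trait"].to_numpy())
        np.testing.assert_allclose(
            [fit.coefficients[k][0] for k in ("intercept", "family_trait", "family_fsiq")],
            beta, atol=1e-10)

    def test_determinism(self):
        table = _noise_cohort(seed=9)
        f1 = fp.fit_model2(table, "srs_total")
        f2 = fp.fit_model2(table, "srs_total")
        assert f1.coefficients == f2.coefficients

    def test_constant_covariate_flags_collinearity(self):
        table = _noise_cohort(seed=10)
        table.data["ses"] = 50.0
        with pytest.warns(UserWarning, match="ill-conditioned"):
            fit = fp.fit_model2(table, "srs_total")
        assert fit.collinear

    def test_min_complete_cases_enforced(self):
        table = _noise_cohort(seed=11, n_families=6)
        table.data.loc[:, "ses"] = np.nan
        with pytest.raises(DegenerateDataError):
            fp.fit_model2(table, "srs_total")

    def test_r2_monotone_in_predictors(self):
        """Unadjusted R^2 never decreases when predictors are added (same rows)."""
        table = _noise_cohort(seed=12)
        fit1, fit2, _ = fp.anova_gate(table, "srs_total")
        assert fit2.r2 >= fit1.r2 - 1e-12
        assert fit1.family_ids == fit2.family_ids


class TestComparison:
    def test_partial_f_matches_independent_oracles(self):
        table = _noise_cohort(seed=13)
        fit1, fit2, cmp_ = fp.anova_gate(table, "srs_total")
        # oracle 1: residual sums recomputed by lstsq
        frame = design_frame(table, "srs_total").loc[list(fit2.family_ids)]
        y = frame["proband_trait"].to_numpy()

        def rss(cols):
            X = np.column_stack([np.ones(len(frame))] + [frame[c] for c in cols])
            resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
            return float(resid @ resid)

        ss1 = rss(list(fit1.predictors))
        ss2 = rss(list(fit2.predictors))
        d = len(fit2.predictors) - len(fit1.predictors)
        df2 = len(frame) - len(fit2.predictors) - 1
        f_oracle = ((ss1 - ss2) / d) / (ss2 / df2)
        assert abs(cmp_.f_statistic - f_oracle) < 1e-9
        # oracle 2: statsmodels anova_lm on the same two fits
        X1 = sm.add_constant(frame[list(fit1.predictors)])
        X2 = sm.add_constant(frame[list(fit2.predictors)])
        tab = anova_lm(sm.OLS(y, X1).fit(), sm.OLS(y, X2).fit())
        assert abs(cmp_.f_statistic - tab["F"].iloc[1]) < 1e-9
        assert abs(cmp_.p - tab["Pr(>F)"].iloc[1]) < 1e-9

    def test_identical_models_give_f0_p1(self):
        table = _noise_cohort(seed=14)
        fit1, _, _ = fp.anova_gate(table, "srs_total")
        same = compare_models(
            fit1, fp.ModelFit(**{**fit1.__dict__,
                                 "predictors": fit1.predictors + ("extra",),
                                 "residual_ss": fit1.residual_ss,
                                 "df_resid": fit1.df_resid - 1}))
        assert same.f_statistic == 0.0 and same.p == 1.0

    def test_mismatched_rows_rejected(self):
        t1, t2 = _noise_cohort(seed=15), _noise_cohort(seed=16)
        pb = t2.data["role"] == "proband"
        t2.data.loc[t2.data.index[pb][:10], "ses"] = np.nan  # shrink t2's rows
        f1, _, _ = fp.anova_gate(t1, "srs_total")
        _, f2b, _ = fp.anova_gate(t2, "srs_total")
        with pytest.raises(ValueError, match="identical"):
            compare_models(f1, f2b)

    def test_non_nested_rejected(self):
        table = _noise_cohort(seed=17)
        fit1, fit2, _ = fp.anova_gate(table, "srs_total")
        with pytest.raises(ValueError, match="nested"):
            compare_models(fit2, fit1)

    def test_pure_noise_predictors_reject_at_5pct(self):
        """Covariates with zero true effect pass the ANOVA gate ~5% of the time."""
        hits, total = 0, 400
        for rep in range(total):
            table = _noise_cohort(seed=100_000 + rep)
            _, _, cmp_ = fp.anova_gate(table, "srs_total")
            hits += cmp_.significant
        rate = hits / total
        assert abs(rate - 0.05) < 0.035  # ~3.2 MC SEs at 400 replicates


class TestCrossTraitEffect:
    def test_beta2_sign_recovered_under_coupling(self):
        """Negative FSIQ->SRS coupling yields a negative family-FSIQ term."""
        neg = 0
        for rep in range(20):
            table = _noise_cohort(seed=200_000 + rep, n_families=500, srs_beta=-0.5)
            fit = fp.fit_model1(table, "srs_total")
            est, _, p = fit.coefficients["family_fsiq"]
            neg += est < 0 and p < 0.05
        assert neg >= 19

    def test_model1_beats_univariate_r2_under_coupling(self):
        table = _noise_cohort(seed=300_001, n_families=500, srs_beta=-0.5)
        fit1 = fp.fit_model1(table, "srs_total")
        uni = fp.fit_offset_model(fp.make_pairs(table, "srs_total"))
        assert fit1.adj_r2 > uni.adj_r2

    def test_beta2_null_rejection_rate(self):
        hits, total = 0, 300
        for rep in range(total):
            table = _noise_cohort(seed=400_000 + rep)
            fit = fp.fit_model1(table, "srs_total")
            hits += fit.coefficients["family_fsiq"][2] < 0.05
        assert abs(hits / total - 0.05) < 0.04


class TestCompleteCase:
    def test_no_missingness_matches_full_fit(self):
        table = _noise_cohort(seed=18)
        table.data["role"].eq("mother")  # cohort already has full covariates
        cc = fp.complete_case_univariate(table, "srs_total")
        full = fp.fit_offset_model(fp.make_pairs(table, "srs_total"))
        assert cc.n == full.n
        assert cc.offset == pytest.approx(full.offset, abs=1e-12)

    def test_covariate_missingness_halves_n(self):
        table = _noise_cohort(seed=19, n_families=400)
        rng = np.random.default_rng(0)
        pb = table.data["role"] == "proband"
        drop = pb & (rng.random(len(table.data)) < 0.5)
        table.data.loc[drop, "ses"] = np.nan
        cc = fp.complete_case_univariate(table, "srs_total")
        frac = cc.n / 400
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 400)
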