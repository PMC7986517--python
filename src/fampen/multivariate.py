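"""Cross-trait and covariate extensions of the univariate penetrance model.

Two nested ordinary-least-squares extensions per outcome trait:

* **Model 1** adds the family FSIQ score to the family score of the outcome
  trait, testing whether familial general cognitive ability cross-predicts
  proband variation in other traits (the ``family_fsiq`` coefficient is
  tested against 0);
* **Model 2** further adds family socioeconomic status (SES index and
  MacArthur ladder rung) and proband perinatal covariates (birth weight,
  gestation length, maternal age).

The two are compared by a nested partial-F (ANOVA) on an identical
complete-case row set; a significant F is required before Model 2's
individual coefficients are interpreted. Complete-case univariate refits on
Model 2's rows allow a like-for-like comparison of explained variance.

OLS fitting delegates to statsmodels; the partial-F is computed here from
residual sums of squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import FamilyTable
from .exceptions import DegenerateDataError
from .regression import RegressionResult, TraitPairs, fit_offset_model, make_pairs

MODEL1_EXTRA = ("family_fsiq",)
MODEL2_EXTRA = ("ses", "macarthur", "birth_weight", "gestation_weeks", "maternal_age")
_COND_LIMIT = 1e8  # design condition number above which a fit is flagged collinear


@dataclass
class ModelFit:
    """One fitted OLS model on a complete-case family set."""

    outcome: str
    predictors: tuple[str, ...]
    coefficients: dict[str, tuple[float, float, float]]  # name -> (est, se, p)
    r2: float
    adj_r2: float
    n_complete: int
    residual_ss: float
    df_resid: int
    family_ids: tuple[str, ...]
    collinear: bool = False


@dataclass
class ModelComparison:
    """Nested partial-F comparison of two OLS fits on identical rows."""

    f_statistic: float
    p: float
    df_num: int
    df_den: int
    delta_adj_r2: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def design_frame(table: FamilyTable, trait: str) -> pd.DataFrame:
    """Per-family outcome/predictor frame for the extended models.

    Columns: ``proband_trait``, ``family_trait``, ``family_fsiq`` and the
    five covariates, indexed by family id. Rows are not yet filtered for
    completeness.
    """
    frame = pd.DataFrame({
        "proband_trait": table.proband_scores(trait),
        "family_trait": table.family_scores(trait),
        "family_fsiq": table.family_scores("fsiq"),
    })
    return frame.join(table.covariates())


def _fit_ols(frame: pd.DataFrame, outcome: str, predictors: tuple[str, ...],
             label: str) -> ModelFit:
    sub = frame[[outcome, *predictors]].dropna()
    y = sub[outcome].to_numpy(dtype=float)
    X = sm.add_constant(sub[list(predictors)].to_numpy(dtype=float), has_constant="add")
    res = sm.OLS(y, X).fit()
    cond = np.linalg.cond(X)
    collinear = bool(cond > _COND_LIMIT or np.linalg.matrix_rank(X) < X.shape[1])
    if collinear:
        warnings.warn(
            f"{label} for {outcome!r}: ill-conditioned design (cond={cond:.2g}); "
            "coefficients may be unstable", stacklevel=3)
    names = ("intercept", *predictors)
    coeffs = {
        name: (float(res.params[i]), float(res.bse[i]), float(res.pvalues[i]))
        for i, name in enumerate(names)
    }
    return ModelFit(
        outcome=outcome, predictors=predictors, coefficients=coeffs,
        r2=float(res.rsquared), adj_r2=float(res.rsquared_adj),
        n_complete=int(res.nobs), residual_ss=float(res.ssr),
        df_resid=int(res.df_resid), family_ids=tuple(sub.index), collinear=collinear,
    )


def fit_model1(table: FamilyTable, trait: str, min_n: int = 6) -> ModelFit:
    """OLS of the proband trait on its family score plus family FSIQ."""
    frame = design_frame(table, trait)
    fit = _fit_ols_checked(frame, ("family_trait",) + MODEL1_EXTRA, trait, min_n, "Model 1")
    return fit


def fit_model2(table: FamilyTable, trait: str, min_n: int = 10) -> ModelFit:
    """Model 1 plus SES, MacArthur ladder and perinatal covariates."""
    frame = design_frame(table, trait)
    preds = ("family_trait",) + MODEL1_EXTRA + MODEL2_EXTRA
    return _fit_ols_checked(frame, preds, trait, min_n, "Model 2")


def _fit_ols_checked(frame: pd.DataFrame, predictors: tuple[str, ...],
                     trait: str, min_n: int, label: str) -> ModelFit:
    n = len(frame[["proband_trait", *predictors]].dropna())
    if n < min_n:
        raise DegenerateDataError(
            f"{label} for {trait!r} needs >= {min_n} complete cases, got {n}")
    fit = _fit_ols(frame, "proband_trait", predictors, label)
    fit = ModelFit(**{**fit.__dict__, "outcome": trait})
    return fit


def compare_models(fit1: ModelFit, fit2: ModelFit) -> ModelComparison:
    """Partial F-test of the reduced model ``fit1`` against the full ``fit2``.

    ``F = ((SS1 - SS2)/d) / (SS2/df2)`` with ``d`` the number of added
    predictors; requires genuine nesting and an identical row set.
    """
    if not set(fit1.predictors) < set(fit2.predictors):
        raise ValueError("fit1 must be strictly nested in fit2")
    if fit1.family_ids != fit2.family_ids:
        raise ValueError(
            "model comparison requires both fits on the identical complete-case rows; "
            "refit the reduced model on the full model's rows first")
    df_num = fit1.df_resid - fit2.df_resid
    if df_num <= 0 or fit2.df_resid <= 0:
        raise ValueError("invalid degrees of freedom for the comparison")
    num = max(fit1.residual_ss - fit2.residual_ss, 0.0) / df_num
    den = fit2.residual_ss / fit2.df_resid
    f = num / den if den > 0 else float("inf")
    p = float(stats.f.sf(f, df_num, fit2.df_resid)) if np.isfinite(f) else 0.0
    if f == 0.0:
        p = 1.0
    return ModelComparison(
        f_statistic=float(f), p=p, df_num=df_num, df_den=fit2.df_resid,
        delta_adj_r2=fit2.adj_r2 - fit1.adj_r2,
    )


def anova_gate(table: FamilyTable, trait: str) -> tuple[ModelFit, ModelFit, ModelComparison]:
    """Fit Models 1 and 2 on Model 2's complete cases and compare them.

    Model 1 is refit on exactly the rows Model 2 retains, so the nested F
    is valid; returns (model1 refit, model2, comparison).
    """
    fit2 = fit_model2(table, trait)
    frame = design_frame(table, trait).loc[list(fit2.family_ids)]
    fit1 = _fit_ols(frame, "proband_trait", ("family_trait",) + MODEL1_EXTRA, "Model 1")
    fit1 = ModelFit(**{**fit1.__dict__, "outcome": trait})
    return fit1, fit2, compare_models(fit1, fit2)


def complete_case_univariate(table: FamilyTable, trait: str) -> RegressionResult:
    """Univariate penetrance refit restricted to Model 2's complete cases."""
    fit2 = fit_model2(table, trait)
    pairs = make_pairs(table, trait)
    keep = [i for i, fid in enumerate(pairs.family_ids) if fid in set(fit2.family_ids)]
    if not keep:
        raise DegenerateDataError(f"no complete cases for {trait!r}")
    sub = TraitPairs(
        trait=pairs.trait,
        proband=pairs.proband[keep],
        family=pairs.family[keep],
        family_ids=tuple(pairs.family_ids[i] for i in keep),
    )
    return fit_offset_model(sub)


def model_frame(fits: list[ModelFit], gated: list[bool] | None = None) -> pd.DataFrame:
    """Serialize model fits: one row per coefficient, with fit-level stats."""
    rows = []
    gated = gated if gated is not None else [True] * len(fits)
    for fit, gate in zip(fits, gated):
        for name, (est, se, p) in fit.coefficients.items():
            rows.append({
                "outcome": fit.outcome, "term": name, "estimate": est,
                "se": se, "p": p, "n_complete": fit.n_complete,
                "r2": fit.r2, "adj_r2": fit.adj_r2, "collinear": fit.collinear,
                "gated": gate,
            })
    return pd.DataFrame(rows)
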