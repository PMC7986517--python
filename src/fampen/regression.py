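"""Per-trait proband-family penetrance regression.

The core model: proband and family scores for one trait are both centred at
the mean family score, then the proband score is regressed on the family
score by ordinary least squares::

    (P - mean(F)) = offset + slope * (F - mean(F)) + e

Because the predictor is centred at its own mean, the fitted intercept
equals ``mean(P) - mean(F)`` exactly — the average shift of probands away
from their unaffected relatives, i.e. the quantitative penetrance of the
variant for that trait. The slope measures proband-family coupling and is
tested two-sided on n-2 degrees of freedom against 0 (no linear
relationship; this test is equivalent to the Pearson correlation test) and
against 1 (a stable offset across the whole family-score range). Cohen's d
standardises the offset by the instrument's *normative* SD (15 / 3 / 10),
not a sample SD.

Implemented as a scikit-learn estimator (:class:`PenetranceRegressor`) in
closed form; the per-trait convenience functions wrap it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import FamilyTable
from .exceptions import DegenerateDataError
from .traits import TraitSpec

#: Number of simultaneously analysed traits used for Bonferroni correction.
DEFAULT_N_TRAITS = 12


@dataclass
class TraitPairs:
    """Complete (proband, family score) pairs for one trait."""

    trait: TraitSpec
    proband: np.ndarray
    family: np.ndarray
    family_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.proband = np.asarray(self.proband, dtype=float)
        self.family = np.asarray(self.family, dtype=float)
        if self.proband.shape != self.family.shape:
            raise ValueError("proband and family vectors differ in length")
        if np.isnan(self.proband).any() or np.isnan(self.family).any():
            raise ValueError("pairs must be complete (no missing values)")

    @property
    def n(self) -> int:
        return int(self.proband.size)


@dataclass
class RegressionResult:
    """One trait's row of the univariate penetrance analysis."""

    trait: str
    n: int
    r: float
    p_r: float
    offset: float
    p_offset: float
    cohen_d: float
    slope: float
    slope_se: float
    p_slope_vs0: float
    p_slope_vs1: float
    adj_r2: float
    bonferroni_significant: dict[str, bool] = field(default_factory=dict)


def make_pairs(table: FamilyTable, trait: str) -> TraitPairs:
    """Pair each family's proband value with its family score; drop incomplete."""
    pb = table.proband_scores(trait)
    fam = table.family_scores(trait)
    ok = pb.notna() & fam.notna()
    return TraitPairs(
        trait=table.spec(trait),
        proband=pb[ok].to_numpy(),
        family=fam[ok].to_numpy(),
        family_ids=tuple(pb.index[ok]),
    )


def _t_sf2(t: float, df: int) -> float:
    """Two-sided p-value of a t statistic."""
    return float(2.0 * stats.t.sf(abs(t), df))


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p of a Pearson r via ``t = r sqrt(n-2)/sqrt(1-r^2)`` on n-2 df."""
    if n < 3:
        raise DegenerateDataError(f"need n >= 3, got {n}")
    r = max(-1.0, min(1.0, float(r)))
    if abs(r) == 1.0:
        return 0.0
    df = n - 2
    return _t_sf2(r * math.sqrt(df) / math.sqrt(1.0 - r * r), df)


def adjusted_r2(r2: float, n: int, n_predictors: int = 1) -> float:
    """Adjusted coefficient of determination; may be negative."""
    df = n - n_predictors - 1
    if df <= 0:
        raise DegenerateDataError(f"n={n} too small for {n_predictors} predictor(s)")
    return 1.0 - (1.0 - r2) * (n - 1) / df


class PenetranceRegressor(RegressorMixin, BaseEstimator):
    """Centred OLS of proband score on family score for one trait.

    Parameters
    ----------
    norm_sd : float, optional
        Normative SD of the trait's instrument; when given, the fitted
        offset is also expressed as Cohen's d (``offset / norm_sd``).

    Attributes (after :meth:`fit`)
    ------------------------------
    offset_ : fitted intercept after centring = mean(P) - mean(F), the
        penetrance estimate in score units; ``cohen_d_`` its standardised
        form (NaN when ``norm_sd`` is not set).
    slope_, slope_se_ : proband-family coupling and its classical OLS SE.
    r_, p_r_ : Pearson correlation and its two-sided p (t on n-2 df).
    p_offset_, p_slope_vs0_, p_slope_vs1_ : two-sided t tests on n-2 df of
        the intercept against 0 and the slope against 0 and 1.
    r2_, adj_r2_ : coefficient of determination and its adjusted form
        ``1 - (1 - R^2) (n-1)/(n-2)`` (may be negative).
    family_mean_ : mean family score, the centring point used by ``predict``.
    """

    def __init__(self, norm_sd: float | None = None):
        self.norm_sd = norm_sd

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("X and y have different lengths")
        n = x.size
        if n < 4:
            raise DegenerateDataError(f"need at least 4 pairs, got {n}")
        if np.isnan(x).any() or np.isnan(y).any():
            raise ValueError("missing values are not allowed; filter pairs first")

        xbar = x.mean()
        xc = x - xbar          # centred predictor; mean is 0 up to float error
        yc = y - xbar
        sxx = float(((xc - xc.mean()) ** 2).sum())
        if sxx == 0.0:
            raise DegenerateDataError("zero family-score variance")
        sxy = float(((xc - xc.mean()) * (yc - yc.mean())).sum())
        syy = float(((yc - yc.mean()) ** 2).sum())

        slope = sxy / sxx
        intercept = yc.mean() - slope * xc.mean()
        resid = yc - (intercept + slope * xc)
        rss = float((resid ** 2).sum())
        df = n - 2
        sigma2 = rss / df
        slope_se = math.sqrt(sigma2 / sxx)
        intercept_se = math.sqrt(sigma2 * (1.0 / n + xc.mean() ** 2 / sxx))

        if syy == 0.0:
            raise DegenerateDataError("zero proband-score variance")
        r = sxy / math.sqrt(sxx * syy)
        r = max(-1.0, min(1.0, r))
        if abs(r) == 1.0:
            p_r = 0.0
        else:
            p_r = _t_sf2(r * math.sqrt(df) / math.sqrt(1.0 - r * r), df)

        def p_vs(target: float, est: float, se: float) -> float:
            if se == 0.0:
                return 1.0 if est == target else 0.0
            return _t_sf2((est - target) / se, df)

        r2 = 1.0 - rss / syy
        self.n_ = n
        self.family_mean_ = float(xbar)
        self.offset_ = float(intercept)
        self.offset_se_ = float(intercept_se)
        self.p_offset_ = p_vs(0.0, intercept, intercept_se)
        self.slope_ = float(slope)
        self.slope_se_ = float(slope_se)
        self.p_slope_vs0_ = p_vs(0.0, slope, slope_se)
        self.p_slope_vs1_ = p_vs(1.0, slope, slope_se)
        self.r_ = float(r)
        self.p_r_ = float(p_r)
        self.r2_ = float(r2)
        self.adj_r2_ = float(adjusted_r2(r2, n))
        self.cohen_d_ = (
            float(intercept / self.norm_sd) if self.norm_sd else float("nan"))
        return self

    def predict(self, X):
        check_is_fitted(self, "offset_")
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.family_mean_ + self.offset_ + self.slope_ * (x - self.family_mean_)


# ---------------------------------------------------------------------- #
# functional wrappers
# ---------------------------------------------------------------------- #
def trait_correlation(pairs: TraitPairs) -> tuple[float, float]:
    """Pearson r and its two-sided p (t on n-2 df) for one trait's pairs."""
    if pairs.n < 3:
        raise DegenerateDataError(f"need >=3 pairs for a correlation, got {pairs.n}")
    x, y = pairs.family, pairs.proband
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance on one side of the correlation")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    df = pairs.n - 2
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
    return r, _t_sf2(t, df)


def fit_offset_model(pairs: TraitPairs, spec: TraitSpec | None = None) -> RegressionResult:
    """Fit the centred offset regression for one trait's pairs."""
    spec = spec or pairs.trait
    est = PenetranceRegressor(norm_sd=spec.norm_sd).fit(pairs.family, pairs.proband)
    return RegressionResult(
        trait=spec.name, n=est.n_, r=est.r_, p_r=est.p_r_,
        offset=est.offset_, p_offset=est.p_offset_, cohen_d=est.cohen_d_,
        slope=est.slope_, slope_se=est.slope_se_,
        p_slope_vs0=est.p_slope_vs0_, p_slope_vs1=est.p_slope_vs1_,
        adj_r2=est.adj_r2_,
    )


def bonferroni_adjust(p_values, m: int = DEFAULT_N_TRAITS) -> list[bool]:
    """Flag each two-tailed p as significant iff ``p * m < 0.05``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return [bool(p * m < 0.05) for p in np.asarray(p_values, dtype=float)]


@dataclass
class SkipRecord:
    trait: str
    reason: str


def penetrance_table(
    table: FamilyTable,
    traits: list[str] | None = None,
    m: int | None = None,
) -> tuple[list[RegressionResult], list[SkipRecord]]:
    """Univariate penetrance analysis for every trait in the cohort.

    Traits whose pairs are degenerate or too few are reported as skip
    records rather than aborting the run. Bonferroni flags are attached per
    test family (offset, slope vs 0, slope vs 1), each corrected across
    ``m`` traits (default: the number of traits analysed, 12 for the full
    battery).
    """
    traits = traits if traits is not None else table.trait_names
    results: list[RegressionResult] = []
    skips: list[SkipRecord] = []
    for name in traits:
        try:
            pairs = make_pairs(table, name)
            results.append(fit_offset_model(pairs))
        except DegenerateDataError as exc:
            skips.append(SkipRecord(trait=name, reason=str(exc)))
    m_eff = m if m is not None else max(len(traits), 1)
    flags = {
        "offset": bonferroni_adjust([res.p_offset for res in results], m_eff),
        "slope_vs0": bonferroni_adjust([res.p_slope_vs0 for res in results], m_eff),
        "slope_vs1": bonferroni_adjust([res.p_slope_vs1 for res in results], m_eff),
    }
    for i, res in enumerate(results):
        res.bonferroni_significant = {k: v[i] for k, v in flags.items()}
    return results, skips


def results_frame(results: list[RegressionResult]) -> pd.DataFrame:
    """Serialize regression results to one row per trait."""
    rows = []
    for res in results:
        row = {
            "trait": res.trait, "n": res.n, "r": res.r, "p_r": res.p_r,
            "offset": res.offset, "p_offset": res.p_offset, "cohen_d": res.cohen_d,
            "slope": res.slope, "slope_se": res.slope_se,
            "p_slope_vs0": res.p_slope_vs0, "p_slope_vs1": res.p_slope_vs1,
            "adj_r2": res.adj_r2,
        }
        for key, flag in res.bonferroni_significant.items():
            row[f"bonf_{key}"] = flag
        rows.append(row)
    return pd.DataFrame(rows)
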