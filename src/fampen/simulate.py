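"""Synthetic family-cohort generator with known ground truth.

The generative model mirrors the structure the downstream analysis assumes.
For family *f* and trait *t*:

* a latent family mean ``L_ft ~ Normal(family_mean_t, between_family_sd_t)``;
* each participating relative observes ``L_ft + Normal(0, within_family_sd_t)``;
* the proband observes::

      family_mean_t + offset_t
        + slope_t * (L_ft - family_mean_t)
        + sum_p beta[p -> t] * (L_fp - family_mean_p)
        + sum_c gamma[c, t] * z_fc
        + Normal(0, proband_noise_sd_t)

  where ``offset_t`` is the penetrance shift in score units, ``slope_t`` the
  proband-family coupling, ``beta`` cross-trait couplings (score units per
  score unit of another trait's latent family mean), and ``gamma`` covariate
  effects in score units per covariate SD (``z_fc`` is the standardised
  covariate draw).

Mother, father and sibling rows are present independently with configurable
probabilities (defaults match the XYY cohort: 57/58, 34/58, 24/58). The
pipeline sees only the noisy relative average, never ``L_ft``; recovery
tests must therefore compare slope estimates against the measurement-error-
attenuated value, which :func:`attenuated_slope` and
:func:`proband_family_correlation` provide in closed form.

A single integer seed drives one ``numpy`` generator stream; identical
seeds give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from . import reference
from .cohort import COVARIATE_COLUMNS, FamilyTable, RELATIVE_ROLES
from .exceptions import ValidationError
from .traits import TraitSpec, default_battery

_DEFAULT_AVAILABILITY = {
    role: reference.RELATIVE_COUNTS[role] / reference.N_FAMILIES
    for role in RELATIVE_ROLES
}


@dataclass
class CovariateModel:
    """Means/SDs of the five family covariates and their effects on probands.

    ``effects`` maps ``(covariate, trait) -> score units per covariate SD``;
    all effects default to zero (the XYY study found no significant
    socioeconomic or perinatal contribution).
    """

    means: dict[str, float] = field(default_factory=lambda: {
        "ses": 50.0, "macarthur": 7.0, "birth_weight": 3400.0,
        "gestation_weeks": 39.5, "maternal_age": 31.0,
    })
    sds: dict[str, float] = field(default_factory=lambda: {
        "ses": 20.0, "macarthur": 1.5, "birth_weight": 550.0,
        "gestation_weeks": 1.8, "maternal_age": 5.0,
    })
    effects: dict[tuple[str, str], float] = field(default_factory=dict)

    def validate(self, trait_names: set[str]) -> None:
        for cov in COVARIATE_COLUMNS:
            if cov not in self.means or cov not in self.sds:
                raise ValidationError(f"covariate model lacks {cov!r}")
            if self.sds[cov] < 0:
                raise ValidationError(f"negative SD for covariate {cov!r}")
        for (cov, trait) in self.effects:
            if cov not in COVARIATE_COLUMNS:
                raise ValidationError(f"effect on unknown covariate {cov!r}")
            if trait not in trait_names:
                raise ValidationError(f"effect on unknown trait {trait!r}")


@dataclass
class SimConfig:
    """Generative parameters of a synthetic family cohort.

    Per-trait dictionaries are keyed by trait name; traits absent from a
    dictionary fall back to the stated default. ``family_mean`` centres the
    latent family means and defaults to each trait's normative mean.
    """

    n_families: int = reference.N_FAMILIES
    trait_specs: list[TraitSpec] = field(default_factory=default_battery)
    family_mean: dict[str, float] = field(default_factory=dict)
    between_family_sd: dict[str, float] = field(default_factory=dict)
    within_family_sd: dict[str, float] = field(default_factory=dict)
    proband_offset: dict[str, float] = field(default_factory=dict)
    proband_slope: dict[str, float] = field(default_factory=dict)
    proband_noise_sd: dict[str, float] = field(default_factory=dict)
    cross_trait_beta: dict[tuple[str, str], float] = field(default_factory=dict)
    availability_probs: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_AVAILABILITY))
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    seed: int = 0

    # defaults used when a per-trait dictionary has no entry; between/within
    # default to half the trait's normative SD each, slope to 1, offset and
    # noise-free proband to a pure family signal
    def _per_trait(self, mapping: Mapping[str, float], trait: TraitSpec, default: float) -> float:
        return float(mapping.get(trait.name, default))

    def trait(self, name: str) -> TraitSpec:
        for s in self.trait_specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def validate(self) -> None:
        if self.n_families < 1:
            raise ValidationError("n_families must be >= 1")
        if not self.trait_specs:
            raise ValidationError("trait_specs must be non-empty")
        names = {s.name for s in self.trait_specs}
        if len(names) != len(self.trait_specs):
            raise ValidationError("duplicate trait names in trait_specs")
        for role, p in self.availability_probs.items():
            if role not in RELATIVE_ROLES:
                raise ValidationError(f"availability for unknown role {role!r}")
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"availability probability out of [0,1] for {role!r}")
        for label, mapping in (
            ("between_family_sd", self.between_family_sd),
            ("within_family_sd", self.within_family_sd),
            ("proband_noise_sd", self.proband_noise_sd),
        ):
            for k, v in mapping.items():
                if k not in names:
                    raise ValidationError(f"{label} for unknown trait {k!r}")
                if v < 0:
                    raise ValidationError(f"{label}[{k!r}] must be >= 0")
        for mapping, label in (
            (self.family_mean, "family_mean"),
            (self.proband_offset, "proband_offset"),
            (self.proband_slope, "proband_slope"),
        ):
            for k in mapping:
                if k not in names:
                    raise ValidationError(f"{label} for unknown trait {k!r}")
        for (pred, out) in self.cross_trait_beta:
            if pred not in names or out not in names:
                raise ValidationError(
                    f"cross_trait_beta references unknown trait in {(pred, out)!r}")
        self.covariate_model.validate(names)


@dataclass
class GroundTruth:
    """Realised latent state and the true generative parameters."""

    latent_means: pd.DataFrame            # families x traits
    offsets: pd.Series                    # per trait
    slopes: pd.Series                     # per trait
    cross_trait_beta: dict[tuple[str, str], float]
    covariate_effects: dict[tuple[str, str], float]


def generate_cohort(config: SimConfig) -> tuple[FamilyTable, GroundTruth]:
    """Draw a cohort from ``config``; reproducible for a fixed seed.

    Draw order is fixed (latent means, role availability, relative noise,
    covariates, proband noise), so any two runs with the same seed agree
    bit for bit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    specs = config.trait_specs
    names = [s.name for s in specs]
    n = config.n_families

    anchor = np.array([
        config._per_trait(config.family_mean, s, s.norm_mean) for s in specs])
    between = np.array([
        config._per_trait(config.between_family_sd, s, s.norm_sd / 2) for s in specs])
    within = np.array([
        config._per_trait(config.within_family_sd, s, s.norm_sd / 2) for s in specs])
    offset = np.array([
        config._per_trait(config.proband_offset, s, 0.0) for s in specs])
    slope = np.array([
        config._per_trait(config.proband_slope, s, 1.0) for s in specs])
    noise = np.array([
        config._per_trait(config.proband_noise_sd, s, s.norm_sd / 2) for s in specs])

    latent = anchor + between * rng.standard_normal((n, len(specs)))

    present = {
        role: rng.random(n) < config.availability_probs.get(role, 1.0)
        for role in RELATIVE_ROLES
    }
    rel_values = {
        role: latent + within * rng.standard_normal((n, len(specs)))
        for role in RELATIVE_ROLES
    }

    cov = config.covariate_model
    cov_z = {c: rng.standard_normal(n) for c in COVARIATE_COLUMNS}
    cov_values = {c: cov.means[c] + cov.sds[c] * cov_z[c] for c in COVARIATE_COLUMNS}

    proband = anchor + offset + slope * (latent - anchor)
    for (pred, out), beta in config.cross_trait_beta.items():
        j_out, j_pred = names.index(out), names.index(pred)
        proband[:, j_out] += beta * (latent[:, j_pred] - anchor[j_pred])
    for (c, t), gamma in cov.effects.items():
        proband[:, names.index(t)] += gamma * cov_z[c]
    proband = proband + noise * rng.standard_normal((n, len(specs)))

    fam_ids = [f"F{i + 1:04d}" for i in range(n)]
    frames = []
    pb = pd.DataFrame(proband, columns=names)
    pb.insert(0, "family_id", fam_ids)
    pb.insert(1, "role", "proband")
    for c in COVARIATE_COLUMNS:
        pb[c] = cov_values[c]
    frames.append(pb)
    for role in RELATIVE_ROLES:
        mask = present[role]
        if mask.any():
            rf = pd.DataFrame(rel_values[role][mask], columns=names)
            rf.insert(0, "family_id", np.array(fam_ids)[mask])
            rf.insert(1, "role", role)
            frames.append(rf)
    data = pd.concat(frames, ignore_index=True)

    table = FamilyTable.from_frame(data, specs)
    truth = GroundTruth(
        latent_means=pd.DataFrame(latent, index=fam_ids, columns=names),
        offsets=pd.Series(offset, index=names),
        slopes=pd.Series(slope, index=names),
        cross_trait_beta=dict(config.cross_trait_beta),
        covariate_effects=dict(cov.effects),
    )
    return table, truth


def write_cohort(table: FamilyTable, path) -> None:
    """Write a cohort CSV in the long dialect (``NA`` for missing values)."""
    cols = ["family_id", "role"] + table.trait_names + list(COVARIATE_COLUMNS)
    table.data.loc[:, cols].to_csv(path, index=False, na_rep="NA")


# ---------------------------------------------------------------------- #
# closed-form oracles for recovery tests
# ---------------------------------------------------------------------- #
def attenuated_slope(slope: float, between_sd: float, within_sd: float,
                     n_relatives: int) -> float:
    """Expected regression slope of proband on the noisy relative average.

    The family score carries measurement error ``within_sd**2 / m`` about
    the latent mean, so the estimable slope is the generative slope shrunk
    by the reliability of the family score.
    """
    var_l = between_sd ** 2
    var_f = var_l + within_sd ** 2 / n_relatives
    return slope * var_l / var_f


def proband_family_correlation(slope: float, between_sd: float, within_sd: float,
                               proband_noise_sd: float, n_relatives: int) -> float:
    """Population proband-family Pearson correlation implied by the model.

    With all ``m`` relatives present, ``cov(P, F) = slope * between_sd**2``,
    ``var(F) = between_sd**2 + within_sd**2/m`` and
    ``var(P) = slope**2 * between_sd**2 + proband_noise_sd**2``.
    """
    var_l = between_sd ** 2
    var_f = var_l + within_sd ** 2 / n_relatives
    var_p = slope ** 2 * var_l + proband_noise_sd ** 2
    if var_f == 0 or var_p == 0:
        raise ZeroDivisionError("degenerate variance in correlation oracle")
    return slope * var_l / np.sqrt(var_f * var_p)


# ---------------------------------------------------------------------- #
# XYY-like preset
# ---------------------------------------------------------------------- #
def xyy_like_config(n_families: int = reference.N_FAMILIES, seed: int = 0,
                    icc_cognitive: float = 0.5, icc_behavioral: float = 0.3,
                    ) -> SimConfig:
    """Preset emulating the published XYY cohort.

    Per-trait parameters are derived at call time from the published
    summary numbers: the latent family mean centres on the mean of the
    three relative-role means, the total relative variance matches the mean
    per-role variance (split between/within by an intraclass correlation of
    0.5 for cognitive and 0.3 for behavioural traits — placeholders, since
    the study does not report this split), offsets and slopes are the
    published penetrance offsets and regression slopes, and the proband
    noise SD is set so the proband marginal SD matches the published one.
    Three negative family-IQ -> proband-SRS couplings reproduce the
    reported protective cross-trait effect.
    """
    marg = reference.role_marginals().set_index(["trait", "role"])
    uni = reference.univariate_summary()
    specs = default_battery()
    cognitive = {"fsiq", "vocabulary", "matrix_reasoning"}

    family_mean, between, within, offs, slopes, noise = {}, {}, {}, {}, {}, {}
    for s in specs:
        rel_means = [marg.loc[(s.name, r), "mean"] for r in RELATIVE_ROLES]
        rel_vars = [marg.loc[(s.name, r), "sd"] ** 2 for r in RELATIVE_ROLES]
        family_mean[s.name] = float(np.mean(rel_means))
        icc = icc_cognitive if s.name in cognitive else icc_behavioral
        total_var = float(np.mean(rel_vars))
        between[s.name] = float(np.sqrt(icc * total_var))
        within[s.name] = float(np.sqrt((1 - icc) * total_var))
        offs[s.name] = float(uni.loc[s.name, "offset"])
        slopes[s.name] = float(uni.loc[s.name, "slope"])
        pb_var = float(marg.loc[(s.name, "proband"), "sd"] ** 2)
        resid = pb_var - slopes[s.name] ** 2 * between[s.name] ** 2
        noise[s.name] = float(np.sqrt(max(resid, (0.25 * s.norm_sd) ** 2)))

    beta = {
        ("fsiq", "srs_total"): -0.25,
        ("fsiq", "srs_communication"): -0.25,
        ("fsiq", "srs_sci"): -0.25,
    }
    return SimConfig(
        n_families=n_families,
        trait_specs=specs,
        family_mean=family_mean,
        between_family_sd=between,
        within_family_sd=within,
        proband_offset=offs,
        proband_slope=slopes,
        proband_noise_sd=noise,
        cross_trait_beta=beta,
        seed=seed,
    )
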