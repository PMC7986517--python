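"""Family trait tables: data model, readers/validators, score aggregation.

The cohort container is a long-format table, one row per individual, keyed
by ``family_id`` and ``role`` (proband / mother / father / sibling), with
one column per trait and five family-level covariate columns. Aggregation
rules implemented here:

* **family score** — unweighted mean of a trait over all available
  non-proband relatives (missing if no relative has the trait);
* **parent score** — mother/father mean, or the single participating
  parent's value (siblings never contribute);
* **z-scoring with polarity orientation** — sample z-score over non-missing
  values, negated for ``lower_is_impaired`` traits so higher always
  indexes greater impairment.

Missingness is handled per trait: a family enters a trait's analysis iff
both its proband value and its family score exist for that trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, FormatError, ValidationError
from .traits import Polarity, Scale, TraitSpec

ROLES = ("proband", "mother", "father", "sibling")
RELATIVE_ROLES = ("mother", "father", "sibling")
PARENT_ROLES = ("mother", "father")

#: Family-level covariate columns of the cohort dialect. ``ses`` and
#: ``macarthur`` describe the family; the other three are proband perinatal
#: variables carried on the family.
COVARIATE_COLUMNS = ("ses", "macarthur", "birth_weight", "gestation_weeks", "maternal_age")
_NONNEGATIVE_COVARIATES = ("birth_weight", "gestation_weeks", "maternal_age")
RESERVED_COLUMNS = ("family_id", "role", "age") + COVARIATE_COLUMNS
_MISSING_TOKENS = ["NA", ""]


@dataclass
class FamilyTable:
    """A validated cohort: long-format individual rows plus trait specs."""

    data: pd.DataFrame
    trait_specs: dict[str, TraitSpec]

    # ------------------------------------------------------------------ #
    # construction & validation
    # ------------------------------------------------------------------ #
    @classmethod
    def from_frame(cls, data: pd.DataFrame, trait_specs: Iterable[TraitSpec]) -> "FamilyTable":
        """Validate a long-format frame against the trait specs.

        Raises :class:`FormatError` for schema problems (missing mandatory
        columns, trait columns absent from the specs) and
        :class:`ValidationError` for invariant violations (unknown roles,
        duplicate probands, non-finite scores, inconsistent covariates).
        """
        specs = {s.name: s for s in trait_specs}
        for col in ("family_id", "role"):
            if col not in data.columns:
                raise FormatError(f"mandatory column {col!r} is missing")
        unknown = [
            c for c in data.columns
            if c not in RESERVED_COLUMNS and c not in specs
        ]
        if unknown:
            raise FormatError(
                f"trait column(s) not in the trait specs: {', '.join(map(repr, unknown))}"
            )

        df = data.copy()
        df["family_id"] = df["family_id"].astype(str)
        bad_roles = sorted(set(df["role"]) - set(ROLES))
        if bad_roles:
            raise ValidationError(f"unknown role(s): {', '.join(map(repr, bad_roles))}")

        counts = df.groupby("family_id")["role"].value_counts().unstack(fill_value=0)
        for role, cap in (("proband", 1), ("mother", 1), ("father", 1)):
            if role in counts and (counts[role] > cap).any():
                offenders = counts.index[counts[role] > cap].tolist()
                raise ValidationError(
                    f"more than one {role} row in family(ies): {', '.join(offenders)}"
                )
        if "proband" not in counts or (counts.get("proband", 0) < 1).any():
            missing = (
                counts.index[counts.get("proband", 0) < 1].tolist()
                if "proband" in counts else sorted(df["family_id"].unique())
            )
            raise ValidationError(f"family(ies) without a proband: {', '.join(missing)}")

        present_traits = [c for c in df.columns if c in specs]
        for col in present_traits:
            df[col] = pd.to_numeric(df[col], errors="raise")
            vals = df[col].to_numpy(dtype=float)
            if np.isinf(vals).any():
                raise ValidationError(f"non-finite value in trait column {col!r}")
        for col in COVARIATE_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
            df[col] = pd.to_numeric(df[col], errors="raise")
        for col in _NONNEGATIVE_COVARIATES:
            if (df[col].dropna() < 0).any():
                raise ValidationError(f"covariate {col!r} must be nonnegative")

        # covariates are family-level: non-missing values must agree within family
        for col in COVARIATE_COLUMNS:
            per_fam = df.groupby("family_id")[col].nunique(dropna=True)
            if (per_fam > 1).any():
                offenders = per_fam.index[per_fam > 1].tolist()
                raise ValidationError(
                    f"inconsistent {col!r} within family(ies): {', '.join(offenders)}"
                )

        # specs with no column in the table are allowed (that trait is absent)
        return cls(data=df.reset_index(drop=True), trait_specs=specs)

    # ------------------------------------------------------------------ #
    # basic accessors
    # ------------------------------------------------------------------ #
    @property
    def trait_names(self) -> list[str]:
        return [c for c in self.data.columns if c in self.trait_specs]

    @property
    def family_ids(self) -> list[str]:
        return sorted(self.data["family_id"].unique())

    @property
    def n_families(self) -> int:
        return self.data["family_id"].nunique()

    def spec(self, trait: str) -> TraitSpec:
        return self.trait_specs[trait]

    def _role_frame(self, roles: tuple[str, ...]) -> pd.DataFrame:
        return self.data[self.data["role"].isin(roles)]

    # ------------------------------------------------------------------ #
    # aggregation
    # ------------------------------------------------------------------ #
    def proband_scores(self, trait: str) -> pd.Series:
        """Proband value per family (NaN where untested)."""
        sub = self._role_frame(("proband",))
        return sub.set_index("family_id")[trait].reindex(self.family_ids)

    def family_scores(self, trait: str) -> pd.Series:
        """Mean of the trait over available non-proband relatives, per family."""
        sub = self._role_frame(RELATIVE_ROLES)
        out = sub.groupby("family_id")[trait].mean()
        return out.reindex(self.family_ids)

    def parent_scores(self, trait: str) -> pd.Series:
        """Mother/father mean (single parent's value if only one), per family."""
        sub = self._role_frame(PARENT_ROLES)
        return sub.groupby("family_id")[trait].mean().reindex(self.family_ids)

    def sibling_scores(self, trait: str) -> pd.Series:
        """Sibling value per family (mean if several siblings participate)."""
        sub = self._role_frame(("sibling",))
        return sub.groupby("family_id")[trait].mean().reindex(self.family_ids)

    def covariates(self) -> pd.DataFrame:
        """One row per family with the five family-level covariates."""
        agg = self.data.groupby("family_id")[list(COVARIATE_COLUMNS)].first()
        return agg.reindex(self.family_ids)


# ---------------------------------------------------------------------- #
# per-family operations
# ---------------------------------------------------------------------- #
def family_score(family_rows: pd.DataFrame, trait: str) -> float:
    """Unweighted mean of ``trait`` over the family's non-proband relatives.

    Returns NaN when no relative carries a value. Invariant to row order.
    """
    rel = family_rows[family_rows["role"].isin(RELATIVE_ROLES)]
    vals = rel[trait].dropna()
    return float(vals.mean()) if len(vals) else float("nan")


def parent_score(family_rows: pd.DataFrame, trait: str) -> float:
    """Mother/father mean for ``trait``; NaN when neither parent has a value."""
    par = family_rows[family_rows["role"].isin(PARENT_ROLES)]
    vals = par[trait].dropna()
    return float(vals.mean()) if len(vals) else float("nan")


def standardize_and_orient(values, spec: TraitSpec) -> pd.Series:
    """Sample z-score oriented so that higher always means more impaired.

    Uses the sample mean/SD (ddof=1) over non-missing entries; entries stay
    missing where they were. ``lower_is_impaired`` traits are negated after
    z-scoring. Requires at least two non-missing values and nonzero spread.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    obs = s.dropna()
    if len(obs) < 2:
        raise DegenerateDataError(
            f"need >=2 non-missing values to z-score {spec.name!r}, got {len(obs)}"
        )
    sd = obs.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError(f"zero sample SD for {spec.name!r}")
    z = (s - obs.mean()) / sd
    return -z if spec.inverted else z


# ---------------------------------------------------------------------- #
# I/O
# ---------------------------------------------------------------------- #
def load_trait_specs(path) -> list[TraitSpec]:
    """Read a trait spec CSV: columns name, scale, polarity [, norm_mean, norm_sd]."""
    df = pd.read_csv(path)
    for col in ("name", "scale", "polarity"):
        if col not in df.columns:
            raise FormatError(f"trait spec file lacks column {col!r}")
    specs = []
    for row in df.itertuples(index=False):
        kwargs = {}
        if "norm_mean" in df.columns and pd.notna(getattr(row, "norm_mean", None)):
            kwargs["norm_mean"] = float(row.norm_mean)
        if "norm_sd" in df.columns and pd.notna(getattr(row, "norm_sd", None)):
            kwargs["norm_sd"] = float(row.norm_sd)
        try:
            specs.append(TraitSpec(row.name, Scale(row.scale), Polarity(row.polarity), **kwargs))
        except ValueError as exc:
            raise FormatError(f"bad trait spec row for {row.name!r}: {exc}") from exc
    return specs


def write_trait_specs(specs: Iterable[TraitSpec], path) -> None:
    rows = [
        {
            "name": s.name, "scale": s.scale.value, "polarity": s.polarity.value,
            "norm_mean": s.norm_mean, "norm_sd": s.norm_sd,
        }
        for s in specs
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_cohort(path, spec_path) -> FamilyTable:
    """Read a cohort CSV (long format, ``NA``/empty = missing) and validate it."""
    specs = load_trait_specs(spec_path)
    try:
        df = pd.read_csv(
            path, na_values=_MISSING_TOKENS, keep_default_na=False,
            dtype={"family_id": str},
        )
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot read cohort file {path!r}: {exc}") from exc
    return FamilyTable.from_frame(df, specs)


def wide_to_long(df: pd.DataFrame) -> pd.DataFrame:
    """Pivot a wide cohort frame to the long dialect.

    Wide format: one row per family, trait columns named ``<role>_<trait>``
    (e.g. ``proband_fsiq``, ``mother_srs_total``), covariate columns as in
    the long dialect. Returns one row per individual.
    """
    if "family_id" not in df.columns:
        raise FormatError("mandatory column 'family_id' is missing")
    covs = [c for c in COVARIATE_COLUMNS if c in df.columns]
    rows = []
    for _, rec in df.iterrows():
        by_role: dict[str, dict] = {}
        for col in df.columns:
            if col == "family_id" or col in covs:
                continue
            role, _, trait = col.partition("_")
            if role not in ROLES or not trait:
                raise FormatError(f"wide column {col!r} is not <role>_<trait>")
            if pd.notna(rec[col]):
                by_role.setdefault(role, {})[trait] = rec[col]
        by_role.setdefault("proband", {})
        for role, traits in by_role.items():
            row = {"family_id": rec["family_id"], "role": role, **traits}
            if role == "proband":
                row.update({c: rec[c] for c in covs})
            rows.append(row)
    return pd.DataFrame(rows)
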