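import numpy as np
import pandas as pd
import pytest

from fampen import FamilyTable, SimConfig, TraitSpec, generate_cohort, xyy_like_config
from fampen.traits import Polarity, Scale


@pytest.fixture(scope="session")
def fsiq_spec():
    return TraitSpec("fsiq", Scale.standard, Polarity.lower_is_impaired)


@pytest.fixture(scope="session")
def srs_spec():
    return TraitSpec("srs_total", Scale.tscore, Polarity.higher_is_impaired)


@pytest.fixture
def two_family_frame():
    """Hand-built two-family long frame with some missingness."""
    return pd.DataFrame([
        {"family_id": "A", "role": "proband", "fsiq": 80.0, "srs_total": 75.0,
         "ses": 45.0, "macarthur": 6.0, "birth_weight": 3300.0,
         "gestation_weeks": 39.0, "maternal_age": 30.0},
        {"family_id": "A", "role": "mother", "fsiq": 106.0, "srs_total": 48.0},
        {"family_id": "A", "role": "father", "fsiq": 110.0, "srs_total": 52.0},
        {"family_id": "A", "role": "sibling", "fsiq": 104.0, "srs_total": np.nan},
        {"family_id": "B", "role": "proband", "fsiq": 92.0, "srs_total": 60.0,
         "ses": 55.0, "macarthur": 8.0, "birth_weight": 3600.0,
         "gestation_weeks": 40.0, "maternal_age": 28.0},
        {"family_id": "B", "role": "mother", "fsiq": 100.0, "srs_total": 44.0},
    ])


@pytest.fixture
def two_family_table(two_family_frame, fsiq_spec, srs_spec):
    return FamilyTable.from_frame(two_family_frame, [fsiq_spec, srs_spec])


@pytest.fixture(scope="session")
def xyy_table():
    """One default XYY-like synthetic cohort (58 families, 12 traits)."""
    table, _ = generate_cohort(xyy_like_config(seed=20260922))
    return table


def single_trait_config(spec, *, n_families, seed, family_mean=None, between=10.0,
                        within=0.0, offset=0.0, slope=1.0, noise=10.0,
                        availability=None):
    """One-trait SimConfig helper used by recovery and calibration tests."""
    avail = availability if availability is not None else {
        "mother": 1.0, "father": 1.0, "sibling": 1.0}
    return SimConfig(
        n_families=n_families,
        trait_specs=[spec],
        family_mean={} if family_mean is None else {spec.name: family_mean},
        between_family_sd={spec.name: between},
        within_family_sd={spec.name: within},
        proband_offset={spec.name: offset},
        proband_slope={spec.name: slope},
        proband_noise_sd={spec.name: noise},
        availability_probs=avail,
        seed=seed,
    )
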