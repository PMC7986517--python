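"""Trait specifications: score scales, normative moments, impairment polarity.

Every analysed measure is a normed clinical score on one of three scales:
standard scores (population mean 100, SD 15; e.g. FSIQ), scaled scores
(mean 10, SD 3; Wechsler subtests) and T-scores (mean 50, SD 10; SRS-2 and
Conners ADHD scales). Cognitive measures are ``lower_is_impaired``;
behavioural questionnaires are ``higher_is_impaired``. The normative SD is
the denominator of the Cohen's d effect size attached to each penetrance
offset, and the polarity drives the sign flip applied before the
trait-by-relative correlation analysis so that larger always means more
impaired.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Scale(str, enum.Enum):
    """Normed score scale of a clinical instrument."""

    standard = "standard"  # mean 100, SD 15
    scaled = "scaled"      # mean 10, SD 3
    tscore = "tscore"      # mean 50, SD 10


class Polarity(str, enum.Enum):
    """Direction in which a score indexes impairment."""

    higher_is_impaired = "higher_is_impaired"
    lower_is_impaired = "lower_is_impaired"


#: Normative (population) mean and SD for each score scale.
SCALE_NORMS: dict[Scale, tuple[float, float]] = {
    Scale.standard: (100.0, 15.0),
    Scale.scaled: (10.0, 3.0),
    Scale.tscore: (50.0, 10.0),
}


@dataclass(frozen=True)
class TraitSpec:
    """One trait measure: name, scale, normative moments and polarity.

    ``norm_mean``/``norm_sd`` default to the scale's population norms and
    may be overridden for instruments normed differently.
    """

    name: str
    scale: Scale
    polarity: Polarity
    norm_mean: float = field(default=None)  # type: ignore[assignment]
    norm_sd: float = field(default=None)    # type: ignore[assignment]

    def __post_init__(self) -> None:
        scale = Scale(self.scale)
        polarity = Polarity(self.polarity)
        object.__setattr__(self, "scale", scale)
        object.__setattr__(self, "polarity", polarity)
        mean, sd = SCALE_NORMS[scale]
        if self.norm_mean is None:
            object.__setattr__(self, "norm_mean", mean)
        if self.norm_sd is None:
            object.__setattr__(self, "norm_sd", sd)
        if not self.norm_sd > 0:
            raise ValueError(f"norm_sd must be positive, got {self.norm_sd}")

    @property
    def inverted(self) -> bool:
        """True when z-scores must be negated to make higher = more impaired."""
        return self.polarity is Polarity.lower_is_impaired


def default_battery() -> list[TraitSpec]:
    """The 12-trait cognitive/behavioural battery used throughout.

    Three Wechsler cognitive measures (lower is impaired), seven SRS-2
    autism-trait T-scores and two Conners ADHD T-scores (higher is
    impaired).
    """
    lo, hi = Polarity.lower_is_impaired, Polarity.higher_is_impaired
    return [
        TraitSpec("fsiq", Scale.standard, lo),
        TraitSpec("vocabulary", Scale.scaled, lo),
        TraitSpec("matrix_reasoning", Scale.scaled, lo),
        TraitSpec("srs_total", Scale.tscore, hi),
        TraitSpec("srs_awareness", Scale.tscore, hi),
        TraitSpec("srs_cognition", Scale.tscore, hi),
        TraitSpec("srs_communication", Scale.tscore, hi),
        TraitSpec("srs_motivation", Scale.tscore, hi),
        TraitSpec("srs_rirb", Scale.tscore, hi),
        TraitSpec("srs_sci", Scale.tscore, hi),
        TraitSpec("adhd_inattentive", Scale.tscore, hi),
        TraitSpec("adhd_hyperactive", Scale.tscore, hi),
    ]
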