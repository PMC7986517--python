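"""Published XYY family-cohort summary statistics.

The raw clinical data of the XYY cohort (58 families ascertained through a
karyotype-confirmed XYY proband; NIH protocol 89-M-0006) are not public, so
the package carries the published *summary* numbers instead: per-role trait
means/SDs and participation counts, and the per-trait univariate regression
summary (proband-family correlation, penetrance offset, slope and its SE,
adjusted R-squared). These serve two purposes:

* the XYY-like preset of the synthetic generator is parameterised from the
  marginals, so simulated cohorts resemble the study cohort;
* worked-example arithmetic (Cohen's d from an offset, adjusted R-squared
  from r and n, the p-value bound of a correlation) reconstructs derived
  quantities from the primary printed ones.

Offset p-values reported only as a bound (< 2e-16) are stored as that bound.
"""

from __future__ import annotations

import io

import pandas as pd

N_FAMILIES = 58

#: Relatives participating, out of 58 families.
RELATIVE_COUNTS = {"mother": 57, "father": 34, "sibling": 24}

#: Per-trait, per-role score mean/SD and N (proband, sibling, mother, father).
_ROLE_MARGINALS_CSV = """\
trait,role,mean,sd,n
fsiq,proband,86.65,13.96,57
fsiq,sibling,104.17,14.24,24
fsiq,mother,106.3,9.27,56
fsiq,father,109.0,11.76,32
vocabulary,proband,7.11,2.91,45
vocabulary,sibling,10.52,2.33,23
vocabulary,mother,10.82,2.10,56
vocabulary,father,11.5,2.14,32
matrix_reasoning,proband,8.97,3.05,58
matrix_reasoning,sibling,11.29,3.44,24
matrix_reasoning,mother,11.53,1.99,57
matrix_reasoning,father,11.82,2.69,34
srs_total,proband,66.4,13.18,58
srs_total,sibling,45.25,6.42,24
srs_total,mother,49.09,6.46,57
srs_total,father,52.53,7.37,34
srs_awareness,proband,66.67,13.21,58
srs_awareness,sibling,48.62,10.37,24
srs_awareness,mother,52.37,5.91,57
srs_awareness,father,55.91,7.1,34
srs_cognition,proband,65.64,12.72,58
srs_cognition,sibling,46.38,7.44,24
srs_cognition,mother,48.19,7.96,57
srs_cognition,father,50.0,6.56,34
srs_communication,proband,66.34,13.46,58
srs_communication,sibling,45.08,6.14,24
srs_communication,mother,48.75,7.18,57
srs_communication,father,53.0,8.31,34
srs_motivation,proband,60.33,12.05,58
srs_motivation,sibling,46.46,7.56,24
srs_motivation,mother,51.68,9.12,57
srs_motivation,father,54.62,10.01,34
srs_rirb,proband,63.9,14.03,58
srs_rirb,sibling,44.25,4.38,24
srs_rirb,mother,47.02,6.08,57
srs_rirb,father,49.68,7.38,34
srs_sci,proband,66.6,12.75,58
srs_sci,sibling,45.75,7.08,24
srs_sci,mother,49.81,6.68,57
srs_sci,father,53.47,7.6,34
adhd_inattentive,proband,73.15,12.61,55
adhd_inattentive,sibling,55.78,11.42,23
adhd_inattentive,mother,48.26,15.32,57
adhd_inattentive,father,48.06,14.35,34
adhd_hyperactive,proband,65.08,15.47,55
adhd_hyperactive,sibling,53.96,13.60,23
adhd_hyperactive,mother,41.51,10.06,57
adhd_hyperactive,father,43.41,7.62,34
"""

#: Published univariate proband-family regression summary, one row per trait.
#: ``offset`` is the penetrance estimate (score units), ``cohen_d`` the
#: printed bracketed effect size, ``slope``/``slope_se`` the regression
#: coefficient and its standard error, ``proband_n`` the proband count used
#: as the regression n.
_UNIVARIATE_CSV = """\
trait,r,offset,cohen_d,p_offset,slope,slope_se,p_slope_vs0,p_slope_vs1,adj_r2,proband_n
fsiq,0.63,-20.15,-1.34,2e-16,0.94,0.15,1.24e-07,0.684,0.39,57
vocabulary,0.57,-3.78,-1.26,2.05e-13,0.91,0.2,3.98e-05,0.662,0.31,45
matrix_reasoning,0.22,-2.59,-0.86,1.77e-08,0.35,0.2,0.091,0.003,0.03,58
srs_total,-0.065,17.04,1.7,1.03e-13,-0.17,0.34,0.629,0.001,-0.01,58
srs_awareness,-0.26,13.83,1.38,3.67e-11,-0.6,0.29,0.045,1.17e-06,0.05,58
srs_cognition,0.088,17.29,1.73,1.53e-14,0.19,0.28,0.51,0.005,-0.01,58
srs_communication,-0.039,17.185,1.72,1.68e-13,-0.09,0.33,0.774,0.001,-0.02,58
srs_motivation,-0.15,8.49,0.85,1.52e-06,-0.24,0.21,0.26,2.60e-07,0.01,58
srs_rirb,0.056,16.85,1.69,1.34e-12,0.17,0.41,0.678,0.045,-0.01,58
srs_sci,-0.085,16.45,1.65,1.02e-13,-0.2,0.31,0.524,2.75e-04,-0.01,58
adhd_inattentive,0.078,24.25,2.43,2e-16,0.09,0.15,0.57,2.17e-07,-0.01,55
adhd_hyperactive,0.22,21.85,2.19,9.42e-15,0.45,0.28,0.106,0.049,0.03,55
"""


def role_marginals() -> pd.DataFrame:
    """Per-role trait score marginals of the XYY cohort (long format)."""
    return pd.read_csv(io.StringIO(_ROLE_MARGINALS_CSV))


def univariate_summary() -> pd.DataFrame:
    """Published per-trait univariate regression summary, indexed by trait."""
    return pd.read_csv(io.StringIO(_UNIVARIATE_CSV), index_col="trait")
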