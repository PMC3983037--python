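"""Published GREML analyses used as external checks of the approximation theory.

Two compilations of published SNP-based estimates from large case-control
GWAS datasets, with the standard errors their original analyses reported:

* ``CASE_CONTROL_STUDIES`` — univariate observed-scale SNP-heritability
  analyses of eight diseases (multiple sclerosis through ADHD).
* ``BIVARIATE_STUDIES`` — bivariate genetic-correlation analyses of the five
  psychiatric disorders (SCZ, BPD, MDD, ASD, ADHD) on independent samples,
  with observed-scale heritabilities derived from the reported
  liability-scale values.

The table builders recompute the theory-predicted SE for every row from the
study's design parameters alone (sample sizes, observed-scale h2, rG) with
the genome-wide relatedness variance var_pi = 2e-5, for comparison against
the reported values.
"""

from __future__ import annotations

import math

import pandas as pd

from .sampling_variance import VAR_PI_DEFAULT, var_rg_cc_cc

__all__ = [
    "CASE_CONTROL_STUDIES",
    "BIVARIATE_STUDIES",
    "case_control_se_table",
    "genetic_correlation_se_table",
]

# disease, n_cases, n_controls, prevalence, observed-scale h2, reported SE,
# and the theory-predicted SE as printed in the original compilation
CASE_CONTROL_STUDIES: list[dict] = [
    {"disease": "Multiple sclerosis", "n_cases": 1604, "n_controls": 1953,
     "prevalence": 0.001, "h2_obs": 0.851, "se_reported": 0.088, "se_approx_printed": 0.089},
    {"disease": "Alzheimer's disease", "n_cases": 3290, "n_controls": 3849,
     "prevalence": 0.020, "h2_obs": 0.364, "se_reported": 0.049, "se_approx_printed": 0.044},
    {"disease": "Endometriosis", "n_cases": 3154, "n_controls": 6981,
     "prevalence": 0.080, "h2_obs": 0.231, "se_reported": 0.036, "se_approx_printed": 0.031},
    {"disease": "Schizophrenia", "n_cases": 9087, "n_controls": 12171,
     "prevalence": 0.010, "h2_obs": 0.410, "se_reported": 0.015, "se_approx_printed": 0.015},
    {"disease": "Bipolar disorder", "n_cases": 6704, "n_controls": 9031,
     "prevalence": 0.010, "h2_obs": 0.441, "se_reported": 0.021, "se_approx_printed": 0.020},
    {"disease": "MDD", "n_cases": 9041, "n_controls": 9381,
     "prevalence": 0.150, "h2_obs": 0.177, "se_reported": 0.017, "se_approx_printed": 0.017},
    {"disease": "ASD", "n_cases": 3303, "n_controls": 3428,
     "prevalence": 0.010, "h2_obs": 0.310, "se_reported": 0.046, "se_approx_printed": 0.047},
    {"disease": "ADHD", "n_cases": 4163, "n_controls": 12040,
     "prevalence": 0.050, "h2_obs": 0.253, "se_reported": 0.020, "se_approx_printed": 0.020},
]

# pairs of independent case-control studies: per-trait design + rG estimate
BIVARIATE_STUDIES: list[dict] = [
    {"trait_1": "SCZ", "K_1": 0.01, "n_cases_1": 9032, "n_controls_1": 7980, "h2_obs_1": 0.40,
     "trait_2": "BPD", "K_2": 0.01, "n_cases_2": 6664, "n_controls_2": 5258, "h2_obs_2": 0.39,
     "rg": 0.68, "se_reported": 0.044, "se_approx_printed": 0.049},
    {"trait_1": "SCZ", "K_1": 0.01, "n_cases_1": 9051, "n_controls_1": 10385, "h2_obs_1": 0.38,
     "trait_2": "MDD", "K_2": 0.15, "n_cases_2": 8998, "n_controls_2": 7823, "h2_obs_2": 0.16,
     "rg": 0.43, "se_reported": 0.055, "se_approx_printed": 0.057},
    {"trait_1": "SCZ", "K_1": 0.01, "n_cases_1": 9111, "n_controls_1": 12146, "h2_obs_1": 0.41,
     "trait_2": "ASD", "K_2": 0.01, "n_cases_2": 3226, "n_controls_2": 3308, "h2_obs_2": 0.29,
     "rg": 0.16, "se_reported": 0.059, "se_approx_printed": 0.057},
    {"trait_1": "SCZ", "K_1": 0.01, "n_cases_1": 9013, "n_controls_1": 10115, "h2_obs_1": 0.42,
     "trait_2": "ADHD", "K_2": 0.05, "n_cases_2": 4108, "n_controls_2": 9936, "h2_obs_2": 0.22,
     "rg": 0.08, "se_reported": 0.046, "se_approx_printed": 0.045},
    {"trait_1": "BPD", "K_1": 0.01, "n_cases_1": 6665, "n_controls_1": 7408, "h2_obs_1": 0.42,
     "trait_2": "MDD", "K_2": 0.15, "n_cases_2": 8997, "n_controls_2": 7680, "h2_obs_2": 0.17,
     "rg": 0.47, "se_reported": 0.061, "se_approx_printed": 0.063},
    {"trait_1": "BPD", "K_1": 0.01, "n_cases_1": 6704, "n_controls_1": 9030, "h2_obs_1": 0.43,
     "trait_2": "ASD", "K_2": 0.01, "n_cases_2": 3207, "n_controls_2": 3294, "h2_obs_2": 0.31,
     "rg": 0.04, "se_reported": 0.065, "se_approx_printed": 0.061},
    {"trait_1": "BPD", "K_1": 0.01, "n_cases_1": 6656, "n_controls_1": 7041, "h2_obs_1": 0.38,
     "trait_2": "ADHD", "K_2": 0.05, "n_cases_2": 4099, "n_controls_2": 9873, "h2_obs_2": 0.25,
     "rg": 0.05, "se_reported": 0.053, "se_approx_printed": 0.052},
    {"trait_1": "MDD", "K_1": 0.15, "n_cases_1": 9031, "n_controls_1": 9370, "h2_obs_1": 0.17,
     "trait_2": "ASD", "K_2": 0.01, "n_cases_2": 3239, "n_controls_2": 3331, "h2_obs_2": 0.31,
     "rg": 0.05, "se_reported": 0.089, "se_approx_printed": 0.090},
    {"trait_1": "MDD", "K_1": 0.15, "n_cases_1": 8936, "n_controls_1": 8668, "h2_obs_1": 0.16,
     "trait_2": "ADHD", "K_2": 0.05, "n_cases_2": 4098, "n_controls_2": 11233, "h2_obs_2": 0.24,
     "rg": 0.32, "se_reported": 0.071, "se_approx_printed": 0.073},
    {"trait_1": "ASD", "K_1": 0.01, "n_cases_1": 3156, "n_controls_1": 3254, "h2_obs_1": 0.27,
     "trait_2": "ADHD", "K_2": 0.05, "n_cases_2": 4181, "n_controls_2": 12022, "h2_obs_2": 0.23,
     "rg": -0.13, "se_reported": 0.087, "se_approx_printed": 0.090},
]


def case_control_se_table(var_pi: float = VAR_PI_DEFAULT) -> pd.DataFrame:
    """Theory-predicted SE of observed-scale h2 for each published case-control study."""
    rows = []
    for study in CASE_CONTROL_STUDIES:
        n = study["n_cases"] + study["n_controls"]
        se = math.sqrt(2.0 / (n * n * var_pi))
        rows.append({**study, "n_total": n, "se_predicted": se,
                     "se_predicted_3dp": round(se, 3)})
    return pd.DataFrame(rows)


def genetic_correlation_se_table(var_pi: float = VAR_PI_DEFAULT) -> pd.DataFrame:
    """Theory-predicted SE of rG for each published pair of independent case-control studies."""
    rows = []
    for study in BIVARIATE_STUDIES:
        n1 = study["n_cases_1"] + study["n_controls_1"]
        n2 = study["n_cases_2"] + study["n_controls_2"]
        var = var_rg_cc_cc(
            n1, n2, study["rg"],
            h2_obs_1=study["h2_obs_1"], h2_obs_2=study["h2_obs_2"], var_pi=var_pi,
        )
        se = math.sqrt(var)
        rows.append({**study, "n_1": n1, "n_2": n2, "se_predicted": se,
                     "se_predicted_3dp": round(se, 3)})
    return pd.DataFrame(rows)
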