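"""Reference statistics for the Moapa dace habitat-selection analysis.

These are the published model-comparison table and fitted coefficient sets
for Moapa dace (*Moapa coriacea*) in Plummer Springbrook, Moapa Valley
National Wildlife Refuge, Nevada (n = 450 sample locations; 309
pseudo-absences, 141 presences; baseflow 0.071 cms).  They serve two
purposes in this package:

* worked-example inputs — the AIC/Akaike-weight arithmetic, odds ratios,
  and quadratic habitat optima are recomputed from these printed values;
* the default "true" habitat model for the synthetic springbrook
  generator, so simulated fish select depth, velocity and substrate the
  way real dace were observed to.

The best-supported models are Model 1 (depth + Froude + substrate) and
Model 2 (depth + velocity + substrate), both with quadratic terms on the
continuous covariates and substrate dummies coded against the
cobble/boulder class.
"""

from __future__ import annotations

import pandas as pd

from .habitat_model import FittedHabitatModel, ModelTerm

__all__ = [
    "model_selection_table",
    "model1_reference",
    "model2_reference",
    "DACE_N_PRESENCE",
    "DACE_N_ABSENCE",
    "PLUMMER_BASEFLOW_CMS",
]

DACE_N_PRESENCE = 141
DACE_N_ABSENCE = 309
PLUMMER_BASEFLOW_CMS = 0.071

# 13 candidate logistic models, best to worst by AIC.  minus2L is the
# deviance -2L; NPar counts every estimated coefficient; C_hat is the
# Hosmer-Lemeshow statistic (NaN where not reported); OA is overall
# classification accuracy (%) at the 0.3 cutpoint.
_TABLE2_ROWS = [
    (1, 407.461, 8, 423.461, 0.000, 0.484, 0.685, 0.403, 76.20, 0.838, "DEP, FRD, SUB3"),
    (2, 409.241, 8, 425.241, 1.780, 0.199, 0.608, 0.399, 76.20, 0.835, "DEP, VEL, SUB3"),
    (3, 421.035, 3, 427.035, 3.574, 0.081, 0.499, 0.372, 75.70, 0.826, "DEP, FRD"),
    (4, 419.037, 4, 427.037, 3.576, 0.081, 0.797, 0.377, 75.05, 0.826, "DEP, VEL, FRD"),
    (5, 407.284, 10, 427.284, 3.828, 0.072, 0.821, 0.403, 76.30, 0.838, "DEP, FRD, TMP, SUB3"),
    (6, 421.916, 3, 427.916, 4.455, 0.052, 0.499, 0.370, 75.10, 0.823, "DEP"),
    (7, 408.963, 10, 428.963, 5.502, 0.031, 0.488, 0.400, 76.55, 0.835, "DEP, VEL, TMP, SUB3"),
    (8, 494.787, 4, 502.787, 79.326, 0.000, None, 0.188, 69.45, 0.708, "SUB3"),
    (9, 491.440, 8, 507.440, 83.979, 0.000, None, 0.197, 68.65, 0.724, "SUB7"),
    (10, 519.993, 2, 523.993, 100.532, 0.000, 0.040, 0.118, 59.50, 0.664, "FRD"),
    (11, 522.173, 3, 528.173, 104.712, 0.000, 0.247, 0.112, 61.65, 0.670, "VEL"),
    (12, 527.814, 4, 535.814, 112.353, 0.000, None, 0.096, 59.60, 0.598, "FRD3"),
    (13, 559.568, 1, 561.568, 138.107, 0.000, 0.000, 0.000, 54.90, 0.500, "TMP"),
]


def model_selection_table() -> pd.DataFrame:
    """The 13-model comparison table (printed values, best to worst by AIC)."""
    return pd.DataFrame(
        _TABLE2_ROWS,
        columns=["model", "minus2L", "n_par", "AIC", "dAIC", "w", "C_hat",
                 "R2", "OA", "AUC", "variables"],
    ).set_index("model")


_MODEL1_TERMS = (
    ModelTerm("DEP"), ModelTerm("DEP", "square"),
    ModelTerm("FRD"), ModelTerm("FRD", "square"),
    ModelTerm("SUB3", categorical=True),
)

_MODEL1_B = {
    "DEP": 12.745, "DEP_2": -8.956,
    "FRD": 4.778, "FRD_2": -22.941,
    "SUB3_1": 1.134, "SUB3_2": 0.800,
    "Constant": -3.838,
}
_MODEL1_SE = {
    "DEP": 4.402, "DEP_2": 7.822,
    "FRD": 6.065, "FRD_2": 20.594,
    "SUB3_1": 0.442, "SUB3_2": 0.282,
    "Constant": 0.626,
}

_MODEL2_TERMS = (
    ModelTerm("DEP"), ModelTerm("DEP", "square"),
    ModelTerm("SUB3", categorical=True),
    ModelTerm("VEL"), ModelTerm("VEL", "square"),
)

_MODEL2_B = {
    "DEP": 13.935, "DEP_2": -10.923,
    "SUB3_1": 1.126, "SUB3_2": 0.796,
    "VEL": 4.238, "VEL_2": -15.174,
    "Constant": -4.047,
}
_MODEL2_SE = {
    "DEP": 4.426, "DEP_2": 7.746,
    "SUB3_1": 0.447, "SUB3_2": 0.282,
    "VEL": 5.135, "VEL_2": 14.272,
    "Constant": 0.604,
}


def model1_reference() -> FittedHabitatModel:
    """Model 1: depth + Froude + substrate, quadratic depth and Froude terms."""
    return FittedHabitatModel.from_coefficients(
        _MODEL1_TERMS, _MODEL1_B, _MODEL1_SE,
        n_obs=DACE_N_PRESENCE + DACE_N_ABSENCE)


def model2_reference() -> FittedHabitatModel:
    """Model 2: depth + velocity + substrate; the model used for habitat
    mapping, extrapolation, and flow simulations."""
    return FittedHabitatModel.from_coefficients(
        _MODEL2_TERMS, _MODEL2_B, _MODEL2_SE,
        n_obs=DACE_N_PRESENCE + DACE_N_ABSENCE)
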