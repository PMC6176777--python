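"""Published field calibrations used as simulator defaults and cross-checks.

These constants come from a late-season energy-sorghum nitrogen-stress trial
(384 plots, 24 lines x 2 nitrogen treatments x 8 replicates): exponential
regressions of per-plot fresh and dry above-ground biomass (kg per plot) on
traits derived from multispectral aerial imagery, and the Pearson correlation
matrix of the candidate predictors on which predictor admissibility screening
(|r| < 0.69) was performed.

The exponential models have the form ``Y = a * exp(sum_j b_j * x_j)`` with
plant height (PH) in cm, canopy cover (CC) as a fraction, and vegetation
indices unitless.  The simulator uses them as generative trait-to-biomass
links, and parameter-recovery studies refit them from simulated data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import ExponentialModel

__all__ = [
    "FRESH_BIOMASS_SER",
    "FRESH_BIOMASS_MER",
    "DRY_BIOMASS_SER",
    "DRY_BIOMASS_MER",
    "PREDICTOR_CORRELATIONS",
    "ADMISSIBILITY_THRESHOLD",
    "MER_PREDICTOR_SETS",
    "DEFAULT_FRESH_MODEL",
    "DEFAULT_DRY_MODEL",
]


def _m(response, predictors, a, b):
    return ExponentialModel(
        response=response,
        predictors=tuple(predictors),
        a=a,
        b=np.asarray(b, dtype=float),
        method="published",
    )


#: Simple exponential regressions for fresh biomass (kg/plot), keyed by predictor.
FRESH_BIOMASS_SER = {
    "PH": _m("fresh_biomass_kg", ["PH"], 21.22, [0.005]),
    "CC": _m("fresh_biomass_kg", ["CC"], 22.47, [1.618]),
    "NDVI": _m("fresh_biomass_kg", ["NDVI"], 0.31, [7.03]),
    "NDRE": _m("fresh_biomass_kg", ["NDRE"], 14.02, [3.813]),
    "RDVI": _m("fresh_biomass_kg", ["RDVI"], 2.04, [6.973]),
    "RGBVI": _m("fresh_biomass_kg", ["RGBVI"], 6.41, [3.68]),
}

#: Multiple exponential regressions for fresh biomass, keyed by predictor tuple.
FRESH_BIOMASS_MER = {
    ("PH", "CC"): _m("fresh_biomass_kg", ["PH", "CC"], 18.70, [0.004, 0.246]),
    ("NDVI", "RGBVI"): _m("fresh_biomass_kg", ["NDVI", "RGBVI"], 0.26, [6.637, 0.706]),
    ("NDRE", "RGBVI"): _m("fresh_biomass_kg", ["NDRE", "RGBVI"], 1.36, [3.605, 3.571]),
    ("RDVI", "RGBVI"): _m("fresh_biomass_kg", ["RDVI", "RGBVI"], 1.32, [6.41, 1.069]),
    ("PH", "NDRE"): _m("fresh_biomass_kg", ["PH", "NDRE"], 16.54, [0.004, 1.166]),
    ("PH", "RGBVI"): _m("fresh_biomass_kg", ["PH", "RGBVI"], 9.37, [0.004, 1.370]),
    ("CC", "NDVI"): _m("fresh_biomass_kg", ["CC", "NDVI"], 0.31, [0.584, 6.447]),
    ("CC", "NDRE"): _m("fresh_biomass_kg", ["CC", "NDRE"], 5.86, [1.336, 3.486]),
    ("CC", "RDVI"): _m("fresh_biomass_kg", ["CC", "RDVI"], 1.96, [0.434, 6.412]),
    ("PH", "CC", "NDRE"): _m(
        "fresh_biomass_kg", ["PH", "CC", "NDRE"], 10.63, [0.003, 0.6, 1.728]
    ),
}

#: Simple exponential regressions for dry biomass (kg/plot).
DRY_BIOMASS_SER = {
    "PH": _m("dry_biomass_kg", ["PH"], 5.63, [0.004]),
    "CC": _m("dry_biomass_kg", ["CC"], 6.50, [1.42]),
    "NDVI": _m("dry_biomass_kg", ["NDVI"], 0.22, [5.679]),
    "NDRE": _m("dry_biomass_kg", ["NDRE"], 4.46, [3.272]),
    "RDVI": _m("dry_biomass_kg", ["RDVI"], 0.91, [5.869]),
    "RGBVI": _m("dry_biomass_kg", ["RGBVI"], 3.04, [2.726]),
}

#: Multiple exponential regressions for dry biomass.
DRY_BIOMASS_MER = {
    ("PH", "CC"): _m("dry_biomass_kg", ["PH", "CC"], 5.15, [0.004, 0.169]),
    ("NDVI", "RGBVI"): _m("dry_biomass_kg", ["NDVI", "RGBVI"], 0.22, [5.607, 0.130]),
    ("NDRE", "RGBVI"): _m("dry_biomass_kg", ["NDRE", "RGBVI"], 0.86, [3.125, 2.522]),
    ("RDVI", "RGBVI"): _m("dry_biomass_kg", ["RDVI", "RGBVI"], 0.77, [5.664, 0.392]),
    ("PH", "NDRE"): _m("dry_biomass_kg", ["PH", "NDRE"], 5.03, [0.004, 0.545]),
    ("PH", "RGBVI"): _m("dry_biomass_kg", ["PH", "RGBVI"], 4.47, [0.004, 0.384]),
    ("CC", "NDVI"): _m("dry_biomass_kg", ["CC", "NDVI"], 0.22, [0.61, 5.085]),
    ("CC", "NDRE"): _m("dry_biomass_kg", ["CC", "NDRE"], 1.94, [1.222, 3.041]),
    ("CC", "RDVI"): _m("dry_biomass_kg", ["CC", "RDVI"], 0.86, [0.472, 5.278]),
    ("PH", "CC", "NDRE"): _m(
        "dry_biomass_kg", ["PH", "CC", "NDRE"], 3.90, [0.003, 0.345, 0.87]
    ),
}

#: Default generative trait-to-biomass links for the simulator.
DEFAULT_FRESH_MODEL = FRESH_BIOMASS_SER["PH"]
DEFAULT_DRY_MODEL = DRY_BIOMASS_SER["PH"]

_PRED_NAMES = ["PH", "CC", "NDVI", "NDRE", "RDVI", "RGBVI"]
_CORR = np.array(
    [
        # PH    CC    NDVI  NDRE  RDVI  RGBVI
        [1.00, 0.61, 0.74, 0.68, 0.80, 0.54],
        [0.61, 1.00, 0.54, 0.25, 0.57, 0.75],
        [0.74, 0.54, 1.00, 0.90, 0.96, 0.64],
        [0.68, 0.25, 0.90, 1.00, 0.89, 0.26],
        [0.80, 0.57, 0.96, 0.89, 1.00, 0.59],
        [0.54, 0.75, 0.64, 0.26, 0.59, 1.00],
    ]
)

#: Field-measured correlation matrix of the candidate biomass predictors.
PREDICTOR_CORRELATIONS = pd.DataFrame(_CORR, index=_PRED_NAMES, columns=_PRED_NAMES)

#: Pairs with |r| at or above this value are too collinear to share a model.
ADMISSIBILITY_THRESHOLD = 0.69

#: The ten admissible predictor combinations used for the multiple models.
MER_PREDICTOR_SETS = list(FRESH_BIOMASS_MER.keys())
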