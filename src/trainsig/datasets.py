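"""Published reference values from the original 15-week cycling study.

The study that motivates this package fitted the four secondary-signal model
variants to six healthy men training on a cycle ergometer for 15 weeks.
These small tables carry its published per-subject results, used in the
documentation, in worked examples and as inputs to desk-scale reanalyses
(Akaike-weight arithmetic, per-subject optimal-dose computation).  The raw
per-day training data are not redistributed here; users transcribe them to
the documented CSV format to rerun the full fitting battery.
"""

from __future__ import annotations

from .kinds import ModelKind
from .params import ModelParameters

#: Published per-subject AICc for the four variants (columns T, TI, TF, TIF).
REFERENCE_AICC: dict[str, dict[str, float]] = {
    "subject1": {"T": 328.04, "TI": 291.07, "TF": 332.74, "TIF": 293.96},
    "subject2": {"T": 330.27, "TI": 299.27, "TF": 335.22, "TIF": 297.16},
    "subject3": {"T": 323.71, "TI": 312.77, "TF": 296.40, "TIF": 296.83},
    "subject4": {"T": 312.72, "TI": 265.16, "TF": 316.83, "TIF": 263.75},
    "subject5": {"T": 301.99, "TI": 281.39, "TF": 305.55, "TIF": 287.04},
    "subject6": {"T": 351.29, "TI": 312.56, "TF": 353.01, "TIF": 310.10},
}

#: Published per-subject inhibition-model (TI) parameter estimates
#: (k_off 1/day, k_s2 W/day per tu, k_s1 1/day, k_i 1/tu).
REFERENCE_TI_ESTIMATES: dict[str, ModelParameters] = {
    "subject1": ModelParameters(k_off=0.0328, k_s1=0.297, k_s2=0.00845, k_i=0.00199),
    "subject2": ModelParameters(k_off=0.0285, k_s1=0.189, k_s2=0.00462, k_i=0.00246),
    "subject3": ModelParameters(k_off=0.0267, k_s1=0.053, k_s2=0.00071, k_i=0.00148),
    "subject4": ModelParameters(k_off=0.0326, k_s1=0.286, k_s2=0.00783, k_i=0.00213),
    "subject5": ModelParameters(k_off=0.0194, k_s1=0.405, k_s2=0.00695, k_i=0.00201),
    "subject6": ModelParameters(k_off=0.0341, k_s1=1.066, k_s2=0.03751, k_i=0.00211),
}

#: Published median TI estimates across the six subjects, used throughout the
#: documentation and the forward simulations.
MEDIAN_TI_PARAMS = ModelParameters(
    k_off=0.0305, k_s1=0.292, k_s2=0.0074, k_i=0.0021
)

MEDIAN_TI_KIND = ModelKind.TI
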