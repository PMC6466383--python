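"""Published young-children calibration equations and their fit statistics.

Eight equations were developed on 37 four-to-six-year-olds (stair climbing
excluded): for non-ambulatory activity, a free-intercept simple regression
(EQ1), fixed-intercept-0.9 linear fits without and with a sex or age
covariate (EQ2–EQ4), and a fixed-intercept quadratic (EQ5); for ambulatory
activity, a free-intercept simple regression (EQ6) and its sex/age variants
(EQ7, EQ8). The recommended two-regression pair is EQ5 (non-ambulatory) +
EQ6 (ambulatory).

``PUBLISHED_SEE`` holds each equation's standard error of estimate in METs;
the synthetic calibration-sample generator uses these as its default noise
levels.
"""

from __future__ import annotations

import json
from importlib import resources

from .calibration import CalibrationEquation
from .classify import ActivityClass

__all__ = [
    "EQ1", "EQ2", "EQ3", "EQ4", "EQ5", "EQ6", "EQ7", "EQ8",
    "PUBLISHED_SEE",
    "YOUNG_CHILDREN_NON_AMBULATORY",
    "YOUNG_CHILDREN_AMBULATORY",
    "load_equation_set",
]

_POP = "young_children"
_NA = ActivityClass.NON_AMBULATORY
_A = ActivityClass.AMBULATORY

EQ1 = CalibrationEquation("linear", 1.2459, 0.0087, target_class=_NA, population_tag=_POP)
EQ2 = CalibrationEquation("linear_fixed_intercept", 0.9, 0.0103, target_class=_NA,
                          population_tag=_POP)
EQ3 = CalibrationEquation("linear_fixed_intercept_covariate", 0.9, 0.0089,
                          covariate_name="sex", covariate_coeff=0.2180,
                          target_class=_NA, population_tag=_POP)
EQ4 = CalibrationEquation("linear_fixed_intercept_covariate", 0.9, 0.0087,
                          covariate_name="age", covariate_coeff=0.0567,
                          target_class=_NA, population_tag=_POP)
EQ5 = CalibrationEquation("quadratic_fixed_intercept", 0.9, 0.0144,
                          quad_counts=-0.0000147, target_class=_NA, population_tag=_POP)
EQ6 = CalibrationEquation("linear", 1.0012, 0.00370, target_class=_A, population_tag=_POP)
EQ7 = CalibrationEquation("linear_covariate", 0.7585, 0.00368,
                          covariate_name="sex", covariate_coeff=0.1706,
                          target_class=_A, population_tag=_POP)
EQ8 = CalibrationEquation("linear_covariate", 0.8310, 0.00370,
                          covariate_name="age", covariate_coeff=0.0278,
                          target_class=_A, population_tag=_POP)

#: Standard error of estimate (METs) of each published equation.
PUBLISHED_SEE = {
    EQ1: 0.370, EQ2: 0.428, EQ3: 0.361, EQ4: 0.370,
    EQ5: 0.350, EQ6: 0.391, EQ7: 0.383, EQ8: 0.393,
}

#: The recommended two-regression pair for young children.
YOUNG_CHILDREN_NON_AMBULATORY = EQ5
YOUNG_CHILDREN_AMBULATORY = EQ6


def load_equation_set(path=None) -> tuple[CalibrationEquation, CalibrationEquation, str]:
    """Load a (non-ambulatory, ambulatory, population) equation set from JSON.

    Without a path, the bundled young-children set (quadratic fixed-intercept
    + ambulatory linear) is returned. User-supplied files follow the same
    schema and allow other populations (e.g. the elementary-school or adult
    coefficient sets, which are not bundled).
    """
    if path is None:
        raw = resources.files("metcalib").joinpath("data/young_children.json").read_text()
    else:
        with open(path, encoding="utf-8") as fh:
            raw = fh.read()
    d = json.loads(raw)
    pop = d.get("population", "")
    nonamb = CalibrationEquation.from_dict(d["non_ambulatory"], _NA, pop)
    amb = CalibrationEquation.from_dict(d["ambulatory"], _A, pop)
    return nonamb, amb, pop
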