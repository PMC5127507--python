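"""Study-design calculators.

Three small tools used when planning a screening study around a
low-copy-number plasma biomarker:

* a precision-based sample-size chain (required cases -> eligible subjects
  -> recruitment goal under anticipated attrition),
* a plasma-equivalent performance lookup that maps a per-reaction plasma
  volume to a measured operating point (assays putting the same effective
  plasma volume into PCR are expected to perform alike),
* a mass-to-genome-copies conversion for limit-of-detection reasoning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from .errors import ValidationError
from .printed_tables import TABLE6_OPERATING_POINTS

logger = logging.getLogger(__name__)

#: Mass of one diploid human genome in picograms (configurable where used).
PG_PER_DIPLOID_GENOME = 6.6


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs for the precision-based sample-size formula
    N = z^2 p(1-p) / e^2.

    ``p`` is the anticipated positive rate, ``e`` the absolute error
    tolerated around it, ``z`` the normal quantile for the confidence
    level (1.96 for 95%). ``case_fraction`` is the fraction of eligible
    subjects expected to be cases and ``attrition`` the anticipated loss
    to follow-up.
    """

    z: float = 1.96
    p: float = 0.68
    e: float = 0.05
    case_fraction: float = 1.0
    attrition: float = 0.0

    def __post_init__(self):
        if not 0 < self.e < 1:
            raise ValidationError("require 0 < e < 1")
        if not 0 < self.p < 1:
            raise ValidationError("require 0 < p < 1")
        if self.z <= 0:
            raise ValidationError("require z > 0")
        if not 0 < self.case_fraction <= 1:
            raise ValidationError("require 0 < case_fraction <= 1")
        if not 0 <= self.attrition < 1:
            raise ValidationError("require 0 <= attrition < 1")


def required_cases(spec: SampleSizeSpec) -> int:
    """floor(z^2 p (1-p) / e^2) cases for the target precision."""
    return math.floor(spec.z ** 2 * spec.p * (1 - spec.p) / spec.e ** 2)


def required_enrollment(spec: SampleSizeSpec) -> tuple[int, int]:
    """(eligible, recruit_goal): scale cases up by the case fraction, then
    inflate for attrition.

    Rounding convention: floor after each division step, ceiling after the
    attrition inflation — the convention that makes the chain land on
    whole-subject counts without ever under-powering the final goal.
    """
    cases = required_cases(spec)
    eligible = math.floor(cases / spec.case_fraction)
    recruit_goal = math.ceil(eligible * (1 + spec.attrition))
    return eligible, recruit_goal


@dataclass(frozen=True)
class OperatingPoint:
    """A (plasma-equivalent volume, sensitivity, specificity) triple."""

    plasma_equivalent_ml: float
    sensitivity: float
    specificity: float
    source: str = "measured"  # "measured" | "predicted"

    def __post_init__(self):
        if self.plasma_equivalent_ml <= 0:
            raise ValidationError("plasma_equivalent_ml must be > 0")
        for f in (self.sensitivity, self.specificity):
            if not 0 <= f <= 1:
                raise ValidationError("fractions must be in [0, 1]")


#: Measured operating points by per-reaction plasma equivalent: the three
#: pooled triplicate wells under the 2/3 rule (2.7 mL), the single-well
#: assay (1.8 mL), and the triplicate assay's averaged single well (1.0 mL).
MEASURED_OPERATING_POINTS = tuple(
    OperatingPoint(v, sens, spec, source="measured")
    for v, sens, spec in TABLE6_OPERATING_POINTS)


def predict_performance(
        plasma_equivalent_ml: float,
        measured: Sequence[OperatingPoint] = MEASURED_OPERATING_POINTS,
) -> OperatingPoint:
    """Predict an assay configuration's operating point from its plasma
    equivalent.

    The rule is equivalence: a configuration inherits the measured
    operating point with the same per-reaction plasma volume. A volume not
    in the measured set maps to the nearest measured equivalent and is
    flagged (logged) as an extrapolation; equidistant volumes resolve to
    the smaller (conservative) equivalent.
    """
    if plasma_equivalent_ml <= 0:
        raise ValidationError("plasma_equivalent_ml must be > 0")
    if not measured:
        raise ValidationError("measured operating points required")
    nearest = min(measured,
                  key=lambda op: (abs(op.plasma_equivalent_ml
                                      - plasma_equivalent_ml),
                                  op.plasma_equivalent_ml))
    exact = math.isclose(nearest.plasma_equivalent_ml, plasma_equivalent_ml,
                         rel_tol=0, abs_tol=1e-9)
    if exact:
        return nearest
    logger.warning(
        "no measured point at %.2f mL plasma equivalent; extrapolating "
        "from nearest measured volume %.2f mL", plasma_equivalent_ml,
        nearest.plasma_equivalent_ml)
    return OperatingPoint(plasma_equivalent_ml, nearest.sensitivity,
                          nearest.specificity, source="predicted")


def mass_to_copies(concentration_pg_per_ml: float,
                   pg_per_genome: float = PG_PER_DIPLOID_GENOME) -> float:
    """Convert a mass concentration (pg/mL) to genome copies per mL."""
    if concentration_pg_per_ml <= 0:
        raise ValidationError("concentration must be > 0")
    if pg_per_genome <= 0:
        raise ValidationError("pg_per_genome must be > 0")
    return concentration_pg_per_ml / pg_per_genome
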