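"""Deriving minimally acceptable criteria (MAC) for sensitivity and
specificity from quantitative consequences of testing.

Two constructions are supported:

* back-calculating the minimal specificity compatible with a cap on the
  overall test-positivity rate (e.g. an acceptable treatment/prescription
  rate) given the prevalence and a sensitivity floor;
* the minimum positive likelihood ratio implied by a required post-test
  probability of disease, which bounds accuracy from below by a line
  through the origin of ROC space.

The MAC pair defines a rectangular "target region" [mac_sens, 1] x
[mac_spec, 1]; an accuracy point is acceptable when both coordinates are
at or above their MAC (boundary inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .accuracy import _check_proportion, _round_half_away

__all__ = [
    "MACriteria",
    "LRRegion",
    "ROCPoint",
    "MacSpecificityResult",
    "InfeasiblePositivityError",
    "mac_specificity_from_positivity",
    "min_positive_lr",
    "point_in_target_region",
    "point_in_lr_region",
]


@dataclass(frozen=True)
class MACriteria:
    """Minimally acceptable sensitivity and specificity.

    The target region in (sensitivity, specificity) coordinates is the
    rectangle [mac_sensitivity, 1] x [mac_specificity, 1].
    """

    mac_sensitivity: float
    mac_specificity: float

    def __post_init__(self) -> None:
        _check_proportion(self.mac_sensitivity, "mac_sensitivity")
        _check_proportion(self.mac_specificity, "mac_specificity")

    def to_dict(self) -> dict:
        return {
            "mac_sensitivity": self.mac_sensitivity,
            "mac_specificity": self.mac_specificity,
        }


@dataclass(frozen=True)
class ROCPoint:
    """A (sensitivity, specificity) pair; plotted in ROC space as
    (1 - specificity, sensitivity)."""

    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        _check_proportion(self.sensitivity, "sensitivity")
        _check_proportion(self.specificity, "specificity")


@dataclass(frozen=True)
class LRRegion:
    """Accuracy region implied by a minimum positive likelihood ratio.

    ``min_positive_lr`` = [t/(1-t)] * [(1-prev)/prev] where t is the
    post-test probability threshold; the acceptable region is the triangle
    sensitivity >= min_positive_lr * (1 - specificity), which always
    contains the perfect-test corner.
    """

    min_positive_lr: float
    prevalence: float
    post_test_threshold: float

    def to_dict(self) -> dict:
        return {
            "min_positive_lr": self.min_positive_lr,
            "prevalence": self.prevalence,
            "post_test_threshold": self.post_test_threshold,
        }


class InfeasiblePositivityError(ValueError):
    """Raised when the positivity cap is below the true-positive flow alone."""

    def __init__(self, min_achievable: float):
        self.min_achievable = min_achievable
        super().__init__(
            "max_positivity_rate is infeasible: even at perfect specificity the "
            f"positivity rate cannot go below {min_achievable:.6g} "
            "(prevalence x MAC sensitivity)"
        )


@dataclass(frozen=True)
class MacSpecificityResult:
    """Output of the positivity-rate back-calculation.

    ``specificity`` is the minimal acceptable specificity;
    ``specificity_percent`` rounds it to the nearest percent.  The per-100
    bookkeeping fields expose the intermediate arithmetic (expected
    true-positive results per 100 patients, the false positives the cap
    still allows, and the non-diseased headcount they come from).
    """

    specificity: float
    specificity_percent: int
    arithmetic: str
    expected_tp_per_100: float
    allowed_fp_per_100: float
    nondiseased_per_100: float

    def to_dict(self) -> dict:
        return {
            "specificity": self.specificity,
            "specificity_percent": self.specificity_percent,
            "arithmetic": self.arithmetic,
            "expected_tp_per_100": self.expected_tp_per_100,
            "allowed_fp_per_100": self.allowed_fp_per_100,
            "nondiseased_per_100": self.nondiseased_per_100,
        }


def mac_specificity_from_positivity(
    prevalence: float,
    mac_sensitivity: float,
    max_positivity_rate: float,
    arithmetic: str = "continuous",
) -> MacSpecificityResult:
    """Smallest specificity keeping the positivity rate within a cap.

    The positivity rate of a test with sensitivity ``mac_sensitivity`` and
    specificity s at prevalence p is  p*sens + (1-p)*(1-s); solving
    p*sens + (1-p)*(1-s) <= max_positivity_rate for s gives

        s_min = 1 - (max_positivity_rate - p*sens) / (1 - p).

    ``arithmetic='per_hundred_integer'`` instead works in whole patients
    per 100 (rounding half away from zero), reproducing the back-of-the-
    envelope arithmetic used when the cap is, e.g., an acceptable
    prescription rate: expected true positives per 100 are rounded first,
    and the resulting specificity is also reported rounded to the nearest
    percent.
    """
    _check_proportion(prevalence, "prevalence")
    _check_proportion(mac_sensitivity, "mac_sensitivity")
    _check_proportion(max_positivity_rate, "max_positivity_rate")
    if arithmetic not in ("continuous", "per_hundred_integer"):
        raise ValueError("arithmetic must be 'continuous' or 'per_hundred_integer'")

    if arithmetic == "per_hundred_integer":
        tp100 = float(_round_half_away(100.0 * prevalence * mac_sensitivity))
        nondis100 = 100.0 - _round_half_away(100.0 * prevalence)
        allowed_fp = 100.0 * max_positivity_rate - tp100
        if allowed_fp < 0:
            raise InfeasiblePositivityError(tp100 / 100.0)
        allowed_fp = min(allowed_fp, nondis100)
        spec = 1.0 - allowed_fp / nondis100 if nondis100 > 0 else 1.0
    else:
        tp100 = 100.0 * prevalence * mac_sensitivity
        nondis100 = 100.0 * (1.0 - prevalence)
        if max_positivity_rate < prevalence * mac_sensitivity:
            raise InfeasiblePositivityError(prevalence * mac_sensitivity)
        allowed_fp = min(100.0 * max_positivity_rate - tp100, nondis100)
        if nondis100 > 0:
            spec = 1.0 - allowed_fp / nondis100
        else:
            spec = 1.0
    spec = min(max(spec, 0.0), 1.0)
    return MacSpecificityResult(
        specificity=spec,
        specificity_percent=_round_half_away(100.0 * spec),
        arithmetic=arithmetic,
        expected_tp_per_100=tp100,
        allowed_fp_per_100=allowed_fp,
        nondiseased_per_100=nondis100,
    )


def min_positive_lr(post_test_threshold: float, prevalence: float) -> LRRegion:
    """Minimum LR+ needed to push the pre-test probability past a threshold.

    Bayes on the odds scale: post-test odds = pre-test odds x LR+, so the
    LR+ that lands exactly on post-test probability t is
    [t/(1-t)] * [(1-prev)/prev].
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be strictly inside (0, 1)")
    if not 0.0 < post_test_threshold < 1.0:
        raise ValueError("post_test_threshold must be strictly inside (0, 1)")
    lr = (post_test_threshold / (1.0 - post_test_threshold)) * ((1.0 - prevalence) / prevalence)
    return LRRegion(
        min_positive_lr=lr,
        prevalence=prevalence,
        post_test_threshold=post_test_threshold,
    )


def point_in_target_region(point: ROCPoint, mac: MACriteria) -> bool:
    """Is the accuracy point inside the rectangular target region?

    Boundary counts as inside (a point exactly at MAC is acceptable).
    """
    return (
        point.sensitivity >= mac.mac_sensitivity
        and point.specificity >= mac.mac_specificity
    )


def point_in_lr_region(point: ROCPoint, region: LRRegion) -> bool:
    """Is the point in the triangle sens >= min_LR+ x (1 - spec)?

    Points on the specificity = 1 edge with positive sensitivity have an
    infinite LR+ and are always inside.
    """
    if point.specificity == 1.0:
        return point.sensitivity > 0.0 or region.min_positive_lr == 0.0
    return point.sensitivity >= region.min_positive_lr * (1.0 - point.specificity)
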