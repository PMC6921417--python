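"""Descriptive statistics for 2x2 diagnostic accuracy data.

A diagnostic accuracy study cross-classifies an index test against a
reference standard, yielding a contingency table of true/false positives
and negatives.  From it we compute sensitivity, specificity, their
one-sided lower confidence bounds, likelihood ratios and the diagnostic
odds ratio, plus the expected downstream misclassification counts for a
cohort of given size and prevalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import beta
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ContingencyTable",
    "AccuracyEstimate",
    "CohortExpectation",
    "estimate_accuracy",
    "one_sided_lower_bound",
    "expected_cohort",
    "INTERVAL_METHODS",
]

INTERVAL_METHODS = ("clopper_pearson", "wilson")


@dataclass(frozen=True)
class ContingencyTable:
    """Cell counts of an index-test vs reference-standard cross-classification.

    Parameters
    ----------
    tp, fp, fn, tn : int
        True positives, false positives, false negatives, true negatives.
        All must be non-negative integers.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if isinstance(v, bool) or not isinstance(v, (int, np.integer)):
                raise TypeError(f"cell {name!r} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"cell {name!r} must be non-negative, got {v}")
            object.__setattr__(self, name, int(v))

    @property
    def n_diseased(self) -> int:
        """Number of subjects with the target condition (tp + fn)."""
        return self.tp + self.fn

    @property
    def n_nondiseased(self) -> int:
        """Number of subjects without the target condition (fp + tn)."""
        return self.fp + self.tn

    @property
    def n_total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}


@dataclass(frozen=True)
class AccuracyEstimate:
    """Sensitivity/specificity estimates with one-sided lower bounds.

    ``lr_positive`` and ``diagnostic_odds_ratio`` may be ``math.inf`` when a
    denominator cell is zero; ``dor_continuity_corrected`` flags that a 0.5
    correction was applied to every cell before computing the odds ratio.
    """

    sensitivity: float
    specificity: float
    sens_lower: float
    spec_lower: float
    confidence_level: float
    lr_positive: float
    lr_negative: float
    diagnostic_odds_ratio: float
    dor_continuity_corrected: bool = False
    interval_method: str = "clopper_pearson"

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "sens_lower": self.sens_lower,
            "spec_lower": self.spec_lower,
            "confidence_level": self.confidence_level,
            "lr_positive": self.lr_positive,
            "lr_negative": self.lr_negative,
            "diagnostic_odds_ratio": self.diagnostic_odds_ratio,
            "dor_continuity_corrected": self.dor_continuity_corrected,
            "interval_method": self.interval_method,
        }


@dataclass(frozen=True)
class CohortExpectation:
    """Expected cell counts when ``n_tested`` patients at a given prevalence
    are tested by a test of known sensitivity and specificity.

    ``number_needed_to_test`` is the inverse of the positivity rate: the
    expected number of patients tested per positive result (``inf`` when the
    test never comes back positive).
    """

    n_tested: int
    prevalence: float
    expected_tp: float
    expected_fp: float
    expected_fn: float
    expected_tn: float
    positivity_rate: float
    number_needed_to_test: float

    def rounded_counts(self) -> dict:
        """Integer display counts, rounding half away from zero."""
        return {
            k: _round_half_away(v)
            for k, v in {
                "expected_tp": self.expected_tp,
                "expected_fp": self.expected_fp,
                "expected_fn": self.expected_fn,
                "expected_tn": self.expected_tn,
            }.items()
        }

    def to_dict(self) -> dict:
        return {
            "n_tested": self.n_tested,
            "prevalence": self.prevalence,
            "expected_tp": self.expected_tp,
            "expected_fp": self.expected_fp,
            "expected_fn": self.expected_fn,
            "expected_tn": self.expected_tn,
            "positivity_rate": self.positivity_rate,
            "number_needed_to_test": self.number_needed_to_test,
        }


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _check_proportion(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


def one_sided_lower_bound(
    successes: int,
    n: int,
    confidence_level: float = 0.95,
    interval_method: str = "clopper_pearson",
) -> float:
    """One-sided lower confidence bound for a binomial proportion.

    Returns L such that the interval [L, 1] has one-sided coverage
    ``confidence_level``.  The Clopper-Pearson bound inverts the exact
    binomial tail: L solves P(X >= successes | n, L) = 1 - confidence_level
    (and is 0 when there are no successes).  The Wilson bound is the lower
    endpoint of the score interval at the matching one-sided level.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError(f"successes must be in [0, n], got {successes} with n={n}")
    if not 0.0 < confidence_level < 1.0:
        raise ValueError("confidence_level must be in (0, 1)")
    alpha = 1.0 - confidence_level
    if interval_method == "clopper_pearson":
        if successes == 0:
            return 0.0
        # beta.ppf inverts the exact binomial tail equation
        return float(beta.ppf(alpha, successes, n - successes + 1))
    if interval_method == "wilson":
        lo, _ = proportion_confint(successes, n, alpha=2 * alpha, method="wilson")
        return float(max(lo, 0.0))
    raise ValueError(f"unknown interval_method {interval_method!r}; choose from {INTERVAL_METHODS}")


def estimate_accuracy(
    table: ContingencyTable,
    confidence_level: float = 0.95,
    interval_method: str = "clopper_pearson",
) -> AccuracyEstimate:
    """Estimate sensitivity and specificity (with one-sided lower bounds),
    likelihood ratios and the diagnostic odds ratio from a 2x2 table.

    sensitivity = tp/(tp+fn), specificity = tn/(fp+tn),
    LR+ = sens/(1-spec), LR- = (1-sens)/spec, DOR = (tp*tn)/(fp*fn).
    When any cell is zero the DOR uses a 0.5 continuity correction on all
    four cells and the result is flagged.
    """
    if table.n_diseased < 1:
        raise ValueError("empty diseased margin: tp + fn must be >= 1 for sensitivity")
    if table.n_nondiseased < 1:
        raise ValueError("empty non-diseased margin: fp + tn must be >= 1 for specificity")

    sens = table.tp / table.n_diseased
    spec = table.tn / table.n_nondiseased

    sens_lower = one_sided_lower_bound(table.tp, table.n_diseased, confidence_level, interval_method)
    spec_lower = one_sided_lower_bound(table.tn, table.n_nondiseased, confidence_level, interval_method)

    lr_pos = sens / (1.0 - spec) if spec < 1.0 else (math.inf if sens > 0 else math.nan)
    lr_neg = (1.0 - sens) / spec if spec > 0.0 else (math.inf if sens < 1.0 else math.nan)

    if min(table.tp, table.fp, table.fn, table.tn) == 0:
        tp, fp, fn, tn = (c + 0.5 for c in (table.tp, table.fp, table.fn, table.tn))
        dor = (tp * tn) / (fp * fn)
        corrected = True
    else:
        dor = (table.tp * table.tn) / (table.fp * table.fn)
        corrected = False

    return AccuracyEstimate(
        sensitivity=sens,
        specificity=spec,
        sens_lower=sens_lower,
        spec_lower=spec_lower,
        confidence_level=confidence_level,
        lr_positive=lr_pos,
        lr_negative=lr_neg,
        diagnostic_odds_ratio=dor,
        dor_continuity_corrected=corrected,
        interval_method=interval_method,
    )


def expected_cohort(
    sensitivity: float,
    specificity: float,
    prevalence: float,
    n_tested: int,
) -> CohortExpectation:
    """Expected cell counts for a cohort tested by a test of known accuracy.

    With D = n * prevalence diseased patients on average, the expected
    misclassifications are fn = D * (1 - sensitivity) and
    fp = (n - D) * (1 - specificity); counts are reported as reals.
    """
    _check_proportion(sensitivity, "sensitivity")
    _check_proportion(specificity, "specificity")
    _check_proportion(prevalence, "prevalence")
    if n_tested < 1:
        raise ValueError("n_tested must be >= 1")

    n_dis = n_tested * prevalence
    n_non = n_tested * (1.0 - prevalence)
    e_tp = n_dis * sensitivity
    e_fn = n_dis * (1.0 - sensitivity)
    e_tn = n_non * specificity
    e_fp = n_non * (1.0 - specificity)
    pos_rate = (e_tp + e_fp) / n_tested
    nnt = (1.0 / pos_rate) if pos_rate > 0 else math.inf

    return CohortExpectation(
        n_tested=n_tested,
        prevalence=prevalence,
        expected_tp=e_tp,
        expected_fp=e_fp,
        expected_fn=e_fn,
        expected_tn=e_tn,
        positivity_rate=pos_rate,
        number_needed_to_test=nnt,
    )
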