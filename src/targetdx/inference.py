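"""Testing the joint MAC hypothesis on observed 2x2 data.

The study hypotheses are joint:

    H1: sensitivity >= MAC(sens)  and  specificity >= MAC(spec)
    H0: sensitivity <  MAC(sens)  and/or specificity < MAC(spec)

which calls for an intersection-union test (IUT): each component is
tested one-sided at level alpha and the joint null is rejected only when
*both* component nulls are rejected, so the joint p-value is the maximum
of the component p-values.  The IUT controls size at alpha without any
multiplicity adjustment across the two components.  By Clopper-Pearson
duality, rejection is equivalent to both one-sided (1 - alpha) lower
confidence bounds clearing their MAC — the graphical "confidence region
inside the target region" criterion.

For continuous scores, `find_qualifying_thresholds` scans every candidate
positivity threshold and flags which ones put the point estimates (and
the confidence region) inside the target region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import binom

from .accuracy import AccuracyEstimate, ContingencyTable, estimate_accuracy
from .mac import MACriteria, ROCPoint, point_in_target_region

__all__ = [
    "JointTestResult",
    "ThresholdScanRow",
    "EvaluationSummary",
    "joint_mac_test",
    "evaluate_strategies",
    "find_qualifying_thresholds",
    "exact_upper_pvalue",
]


def exact_upper_pvalue(successes: int, n: int, p0: float) -> float:
    """Exact one-sided binomial p-value P(X >= successes | n, p0)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    return float(binom.sf(successes - 1, n, p0))


@dataclass(frozen=True)
class JointTestResult:
    """Outcome of the joint MAC test for one testing strategy."""

    estimate: AccuracyEstimate
    mac: MACriteria
    alpha: float
    p_sensitivity: float
    p_specificity: float
    p_joint: float
    reject_null: bool
    point_in_region: bool
    confidence_region_in_region: bool
    label: str | None = None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "estimate": self.estimate.to_dict(),
            "mac": self.mac.to_dict(),
            "alpha": self.alpha,
            "p_sensitivity": self.p_sensitivity,
            "p_specificity": self.p_specificity,
            "p_joint": self.p_joint,
            "reject_null": self.reject_null,
            "point_in_region": self.point_in_region,
            "confidence_region_in_region": self.confidence_region_in_region,
        }


@dataclass(frozen=True)
class EvaluationSummary:
    """Per-strategy results plus counts of how many met each criterion.

    ``n_point_only`` counts strategies whose point estimates are in the
    target region while the confidence region is not — the "promising but
    underpowered" pattern.  No multiplicity adjustment is applied across
    strategies; each is reported at its own level alpha.
    """

    results: tuple[JointTestResult, ...]
    n_reject: int
    n_point_in_region: int
    n_point_only: int

    def to_dict(self) -> dict:
        return {
            "results": [r.to_dict() for r in self.results],
            "n_reject": self.n_reject,
            "n_point_in_region": self.n_point_in_region,
            "n_point_only": self.n_point_only,
            "multiplicity_adjustment": "none (per-strategy reporting)",
        }


@dataclass(frozen=True)
class ThresholdScanRow:
    """One candidate positivity threshold of a continuous score."""

    threshold: float
    table: ContingencyTable
    sensitivity: float
    specificity: float
    in_region_point: bool
    in_region_ci: bool

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            **self.table.to_dict(),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "in_region_point": self.in_region_point,
            "in_region_ci": self.in_region_ci,
        }


def joint_mac_test(
    table: ContingencyTable,
    mac: MACriteria,
    alpha: float = 0.05,
    interval_method: str = "clopper_pearson",
) -> JointTestResult:
    """Intersection-union test of the joint MAC null on a 2x2 table.

    Component p-values are exact one-sided binomial tails at the MAC
    (P(X >= observed | p = MAC)); the joint p-value is their maximum and
    the null is rejected when it is <= alpha.  The confidence-region flag
    applies the equivalent graphical rule: both one-sided (1 - alpha)
    lower bounds at or above their MAC.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    est = estimate_accuracy(table, confidence_level=1.0 - alpha, interval_method=interval_method)
    p_sens = exact_upper_pvalue(table.tp, table.n_diseased, mac.mac_sensitivity)
    p_spec = exact_upper_pvalue(table.tn, table.n_nondiseased, mac.mac_specificity)
    p_joint = max(p_sens, p_spec)
    reject = p_joint <= alpha
    in_region = point_in_target_region(
        ROCPoint(est.sensitivity, est.specificity), mac
    )
    ci_in_region = (
        est.sens_lower >= mac.mac_sensitivity and est.spec_lower >= mac.mac_specificity
    )
    return JointTestResult(
        estimate=est,
        mac=mac,
        alpha=alpha,
        p_sensitivity=p_sens,
        p_specificity=p_spec,
        p_joint=p_joint,
        reject_null=reject,
        point_in_region=in_region,
        confidence_region_in_region=ci_in_region,
    )


def evaluate_strategies(
    tables: Sequence[tuple[str, ContingencyTable]],
    mac: MACriteria,
    alpha: float = 0.05,
    interval_method: str = "clopper_pearson",
) -> EvaluationSummary:
    """Run the joint MAC test on several labeled testing strategies."""
    if len(tables) < 1:
        raise ValueError("at least one strategy is required")
    labels = [label for label, _ in tables]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate strategy labels: {dupes}")
    results = []
    for label, table in tables:
        res = joint_mac_test(table, mac, alpha, interval_method)
        results.append(
            JointTestResult(**{**res.__dict__, "label": label})
        )
    n_reject = sum(r.reject_null for r in results)
    n_point = sum(r.point_in_region for r in results)
    n_point_only = sum(
        r.point_in_region and not r.confidence_region_in_region for r in results
    )
    return EvaluationSummary(
        results=tuple(results),
        n_reject=n_reject,
        n_point_in_region=n_point,
        n_point_only=n_point_only,
    )


def find_qualifying_thresholds(
    scores: Sequence[float],
    disease_status: Sequence[int],
    mac: MACriteria,
    alpha: float = 0.05,
    direction: str = "higher_positive",
    interval_method: str = "clopper_pearson",
) -> list[ThresholdScanRow]:
    """Scan candidate thresholds of a continuous score for MAC compliance.

    Candidates are the midpoints between adjacent distinct score values
    plus -inf and +inf.  In the ``higher_positive`` direction a score at
    or above the threshold is called positive (closed on the positive
    side); ``lower_positive`` mirrors the rule.  An empty qualifying set
    is a legitimate outcome: it means no threshold makes the test fit for
    its intended use.
    """
    scores_arr = np.asarray(scores, dtype=float)
    status_arr = np.asarray(disease_status, dtype=int)
    if scores_arr.shape != status_arr.shape or scores_arr.ndim != 1:
        raise ValueError("scores and disease_status must be 1-D and the same length")
    if not np.all(np.isfinite(scores_arr)):
        raise ValueError("scores must be finite")
    if not np.isin(status_arr, (0, 1)).all():
        raise ValueError("disease_status must be 0/1")
    n_dis = int(status_arr.sum())
    n_non = int((1 - status_arr).sum())
    if n_dis == 0 or n_non == 0:
        raise ValueError("both diseased and non-diseased subjects are required")
    if direction not in ("higher_positive", "lower_positive"):
        raise ValueError("direction must be 'higher_positive' or 'lower_positive'")

    distinct = np.unique(scores_arr)
    candidates = [-math.inf, *((distinct[:-1] + distinct[1:]) / 2.0), math.inf]

    rows: list[ThresholdScanRow] = []
    for thr in candidates:
        if direction == "higher_positive":
            positive = scores_arr >= thr
        else:
            positive = scores_arr <= thr
        tp = int(np.sum(positive & (status_arr == 1)))
        fn = n_dis - tp
        fp = int(np.sum(positive & (status_arr == 0)))
        tn = n_non - fp
        table = ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)
        res = joint_mac_test(table, mac, alpha, interval_method)
        rows.append(
            ThresholdScanRow(
                threshold=float(thr),
                table=table,
                sensitivity=res.estimate.sensitivity,
                specificity=res.estimate.specificity,
                in_region_point=res.point_in_region,
                in_region_ci=res.confidence_region_in_region,
            )
        )
    return rows
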