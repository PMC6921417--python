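"""Sample size and power for one-sided tests of a binomial proportion
against a minimally acceptable criterion (MAC).

Per accuracy component the study must show, with one-sided type-I error
alpha and the stated power, that the true proportion (sensitivity among
diseased patients, specificity among non-diseased) exceeds its MAC when
the truth equals the expected value.  The normal-approximation sample
size is the classic two-z one-sample formula

    n = ceil( (z_{1-a} * sqrt(mac(1-mac)) + z_{pow} * sqrt(p(1-p)))^2
              / (p - mac)^2 ),        p = expected value,

and the exact-binomial alternative scans n for the smallest size whose
exact one-sided level-alpha test reaches the target power (with a
stability window to guard against the sawtooth of exact power in n).
The two per-group sizes are inflated to a single cohort total through
the prevalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import binom, norm

from .accuracy import _check_proportion
from .mac import MACriteria

__all__ = [
    "DesignSpec",
    "SampleSizeResult",
    "n_for_proportion",
    "sample_size",
    "power_at_n",
    "SIZE_METHODS",
]

SIZE_METHODS = ("normal_approx", "exact_binomial")

# exact power is non-monotone in n; require the target to hold on a window
_EXACT_SCAN_WINDOW = 20
_EXACT_SCAN_MAX_N = 100_000


@dataclass(frozen=True)
class DesignSpec:
    """Design parameters for a targeted diagnostic accuracy study.

    ``alpha`` is the one-sided type-I error rate; ``power`` the target
    probability of rejecting the joint null when both components sit at
    their expected values.  Expected values must strictly exceed their
    MAC or no finite sample size exists.
    """

    alpha: float
    power: float
    expected_sensitivity: float
    expected_specificity: float
    mac: MACriteria
    prevalence: float

    def __post_init__(self) -> None:
        for name in ("alpha", "power"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        _check_proportion(self.expected_sensitivity, "expected_sensitivity")
        _check_proportion(self.expected_specificity, "expected_specificity")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be strictly inside (0, 1)")
        if self.expected_sensitivity <= self.mac.mac_sensitivity:
            raise ValueError(
                "expected_sensitivity must strictly exceed MAC sensitivity "
                "(otherwise no finite sample size exists)"
            )
        if self.expected_specificity <= self.mac.mac_specificity:
            raise ValueError(
                "expected_specificity must strictly exceed MAC specificity "
                "(otherwise no finite sample size exists)"
            )

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "power": self.power,
            "expected_sensitivity": self.expected_sensitivity,
            "expected_specificity": self.expected_specificity,
            "mac": self.mac.to_dict(),
            "prevalence": self.prevalence,
        }


@dataclass(frozen=True)
class SampleSizeResult:
    """Per-group and total sample sizes.

    ``n_total`` inflates the binding per-group requirement through the
    prevalence: max(ceil(n_diseased/prev), ceil(n_nondiseased/(1-prev))).
    Both per-group constraints are retained so reports can print them.
    """

    n_diseased: int
    n_nondiseased: int
    n_total: int
    binding_group: str
    n_total_for_diseased: int
    n_total_for_nondiseased: int

    def to_dict(self) -> dict:
        return {
            "n_diseased": self.n_diseased,
            "n_nondiseased": self.n_nondiseased,
            "n_total": self.n_total,
            "binding_group": self.binding_group,
            "n_total_for_diseased": self.n_total_for_diseased,
            "n_total_for_nondiseased": self.n_total_for_nondiseased,
        }


def _ceil(x: float) -> int:
    # protect against 180.00000000000003-style float noise
    return int(math.ceil(x - 1e-9))


def _critical_count(n: int, mac_value: float, alpha: float) -> int:
    """Smallest success count whose exact one-sided p-value vs mac is <= alpha.

    Returns n + 1 when even n successes cannot reject.
    """
    # P(X >= k | n, mac) = binom.sf(k - 1, n, mac); find smallest such k
    k = int(binom.isf(alpha, n, mac_value))  # first guess near the tail
    while k > 0 and binom.sf(k - 1 - 1, n, mac_value) <= alpha:
        k -= 1
    while k <= n and binom.sf(k - 1, n, mac_value) > alpha:
        k += 1
    return k


def power_at_n(
    n: int,
    mac_value: float,
    true_value: float,
    alpha: float = 0.05,
    method: str = "exact_binomial",
) -> float:
    """Power of the one-sided level-alpha test of H0: p <= mac at a truth.

    Exact method: P(X >= k*) under Binomial(n, true_value) where k* is the
    exact critical count.  Normal method: the closed-form counterpart of
    the two-z sample-size formula.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    _check_proportion(mac_value, "mac_value")
    _check_proportion(true_value, "true_value")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if method == "exact_binomial":
        k_star = _critical_count(n, mac_value, alpha)
        if k_star > n:
            return 0.0
        return float(binom.sf(k_star - 1, n, true_value))
    if method == "normal_approx":
        if true_value in (0.0, 1.0):
            return 1.0 if (true_value > mac_value) else 0.0
        z_a = norm.ppf(1.0 - alpha)
        num = math.sqrt(n) * (true_value - mac_value) - z_a * math.sqrt(mac_value * (1 - mac_value))
        den = math.sqrt(true_value * (1 - true_value))
        return float(norm.cdf(num / den))
    raise ValueError(f"unknown method {method!r}; choose from {SIZE_METHODS}")


def n_for_proportion(
    mac_value: float,
    expected_value: float,
    alpha: float = 0.05,
    power: float = 0.90,
    method: str = "normal_approx",
) -> int:
    """Participants needed in one group so the one-sided lower confidence
    limit is expected to clear the MAC with the stated power."""
    _check_proportion(mac_value, "mac_value")
    _check_proportion(expected_value, "expected_value")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if not 0.0 < power < 1.0:
        raise ValueError("power must be in (0, 1)")
    if expected_value <= mac_value:
        raise ValueError(
            "expected_value must strictly exceed mac_value: no finite n can "
            "demonstrate accuracy above MAC when the truth is at or below it"
        )
    if method == "normal_approx":
        z_a = norm.ppf(1.0 - alpha)
        z_b = norm.ppf(power)
        num = z_a * math.sqrt(mac_value * (1 - mac_value)) + z_b * math.sqrt(
            expected_value * (1 - expected_value)
        )
        return _ceil((num / (expected_value - mac_value)) ** 2)
    if method == "exact_binomial":
        streak_start = None
        streak_len = 0
        for n in range(1, _EXACT_SCAN_MAX_N + 1):
            if power_at_n(n, mac_value, expected_value, alpha, "exact_binomial") >= power:
                if streak_start is None:
                    streak_start = n
                streak_len += 1
                if streak_len > _EXACT_SCAN_WINDOW:
                    return streak_start
            else:
                streak_start = None
                streak_len = 0
        raise RuntimeError("exact sample-size scan exceeded the search limit")
    raise ValueError(f"unknown method {method!r}; choose from {SIZE_METHODS}")


def sample_size(design: DesignSpec, method: str = "normal_approx") -> SampleSizeResult:
    """Per-group sizes for both accuracy components and the cohort total.

    The diseased-group size is driven by the sensitivity pair, the
    non-diseased group by the specificity pair; the total is whichever
    prevalence-inflated constraint binds.
    """
    n_dis = n_for_proportion(
        design.mac.mac_sensitivity, design.expected_sensitivity, design.alpha, design.power, method
    )
    n_non = n_for_proportion(
        design.mac.mac_specificity, design.expected_specificity, design.alpha, design.power, method
    )
    total_dis = _ceil(n_dis / design.prevalence)
    total_non = _ceil(n_non / (1.0 - design.prevalence))
    if total_dis >= total_non:
        binding = "diseased"
        total = total_dis
    else:
        binding = "nondiseased"
        total = total_non
    return SampleSizeResult(
        n_diseased=n_dis,
        n_nondiseased=n_non,
        n_total=total,
        binding_group=binding,
        n_total_for_diseased=total_dis,
        n_total_for_nondiseased=total_non,
    )
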