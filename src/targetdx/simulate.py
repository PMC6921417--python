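"""Monte-Carlo verification of the joint MAC test and the sample-size
procedure.

Synthetic diagnostic accuracy studies are drawn under a known truth
(true sensitivity/specificity, prevalence, cohort size) and the joint
test's rejection rate is measured — its size when the truth sits on the
null boundary, its power when the truth is inside the target region.
With fixed group margins the sensitivity and specificity components are
independent binomials, so the joint power factorizes into the product of
the exact marginal powers; this serves as an analytic cross-check.

Randomness comes from numpy's default generator (PCG64), which is
seedable and platform-stable; the generator identity is recorded in
every report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import binom

from .accuracy import ContingencyTable, _check_proportion, _round_half_away
from .design import DesignSpec, SampleSizeResult, sample_size
from .mac import MACriteria

__all__ = [
    "TruthScenario",
    "SimulationReport",
    "generate_study",
    "operating_characteristics",
    "calibration_sweep",
    "SAMPLING_MODES",
]

SAMPLING_MODES = ("binomial_prevalence", "fixed_margins")
_GENERATOR_ID = "numpy.random.default_rng (PCG64)"


@dataclass(frozen=True)
class TruthScenario:
    """A known truth from which synthetic 2x2 studies are drawn.

    ``binomial_prevalence`` draws the diseased count Binomial(n, prev)
    before drawing the cells, mimicking a single consecutive cohort;
    ``fixed_margins`` fixes it at round(n * prev), mimicking a design that
    recruits the two groups to target.
    """

    true_sensitivity: float
    true_specificity: float
    prevalence: float
    n_total: int
    sampling: str = "binomial_prevalence"
    seed: int = 0

    def __post_init__(self) -> None:
        _check_proportion(self.true_sensitivity, "true_sensitivity")
        _check_proportion(self.true_specificity, "true_specificity")
        _check_proportion(self.prevalence, "prevalence")
        if self.n_total < 2:
            raise ValueError("n_total must be >= 2")
        if self.sampling not in SAMPLING_MODES:
            raise ValueError(f"sampling must be one of {SAMPLING_MODES}")

    def to_dict(self) -> dict:
        return {
            "true_sensitivity": self.true_sensitivity,
            "true_specificity": self.true_specificity,
            "prevalence": self.prevalence,
            "n_total": self.n_total,
            "sampling": self.sampling,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class SimulationReport:
    """Monte-Carlo rejection rate with its own uncertainty.

    ``mc_halfwidth`` is the 95% half-width 1.96 * sqrt(r(1-r)/reps).
    Replicates with an empty diseased or non-diseased margin cannot
    reject and are tallied in ``n_empty_margin`` rather than dropped
    (dropping them would bias power upward at small n x prevalence).
    Mean accuracy is averaged over replicates with non-empty margins.
    """

    n_replicates: int
    rejection_rate: float
    mc_halfwidth: float
    mean_sensitivity: float
    mean_specificity: float
    n_empty_margin: int
    generator: str = _GENERATOR_ID

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "rejection_rate": self.rejection_rate,
            "mc_halfwidth": self.mc_halfwidth,
            "mean_sensitivity": self.mean_sensitivity,
            "mean_specificity": self.mean_specificity,
            "n_empty_margin": self.n_empty_margin,
            "generator": self.generator,
        }


def _draw_margins(scenario: TruthScenario, rng: np.random.Generator, size: int) -> np.ndarray:
    if scenario.sampling == "fixed_margins":
        n_dis = _round_half_away(scenario.n_total * scenario.prevalence)
        return np.full(size, n_dis, dtype=np.int64)
    return rng.binomial(scenario.n_total, scenario.prevalence, size=size).astype(np.int64)


def generate_study(scenario: TruthScenario) -> ContingencyTable:
    """Draw a single synthetic 2x2 study under the scenario's truth.

    Reproducible: the same scenario (including seed) always yields the
    same table.  An empty diseased or non-diseased margin is a valid
    draw; downstream consumers must handle it.
    """
    rng = np.random.default_rng(scenario.seed)
    n_dis = int(_draw_margins(scenario, rng, 1)[0])
    n_non = scenario.n_total - n_dis
    tp = int(rng.binomial(n_dis, scenario.true_sensitivity)) if n_dis > 0 else 0
    tn = int(rng.binomial(n_non, scenario.true_specificity)) if n_non > 0 else 0
    return ContingencyTable(tp=tp, fp=n_non - tn, fn=n_dis - tp, tn=tn)


def operating_characteristics(
    scenario: TruthScenario,
    mac: MACriteria,
    alpha: float = 0.05,
    n_replicates: int = 10_000,
    interval_method: str = "clopper_pearson",
) -> SimulationReport:
    """Rejection rate of the joint MAC test under a known truth.

    Vectorized over replicates: component p-values are the same exact
    one-sided binomial tails the scalar test uses, and a replicate
    rejects when both are <= alpha.
    """
    if n_replicates < 100:
        raise ValueError("n_replicates must be >= 100")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    rng = np.random.default_rng(scenario.seed)
    n_dis = _draw_margins(scenario, rng, n_replicates)
    n_non = scenario.n_total - n_dis
    tp = rng.binomial(n_dis, scenario.true_sensitivity)
    tn = rng.binomial(n_non, scenario.true_specificity)

    # exact one-sided tails P(X >= tp) / P(X >= tn) at the MAC values
    p_sens = binom.sf(tp - 1, n_dis, mac.mac_sensitivity)
    p_spec = binom.sf(tn - 1, n_non, mac.mac_specificity)
    nonempty = (n_dis > 0) & (n_non > 0)
    reject = nonempty & (np.maximum(p_sens, p_spec) <= alpha)

    r = float(reject.mean())
    halfwidth = 1.96 * math.sqrt(r * (1.0 - r) / n_replicates)
    with np.errstate(invalid="ignore", divide="ignore"):
        sens_obs = np.where(n_dis > 0, tp / np.maximum(n_dis, 1), np.nan)
        spec_obs = np.where(n_non > 0, tn / np.maximum(n_non, 1), np.nan)
    return SimulationReport(
        n_replicates=n_replicates,
        rejection_rate=r,
        mc_halfwidth=halfwidth,
        mean_sensitivity=float(np.nanmean(sens_obs)),
        mean_specificity=float(np.nanmean(spec_obs)),
        n_empty_margin=int((~nonempty).sum()),
    )


def calibration_sweep(
    designs: Sequence[DesignSpec],
    n_replicates: int = 10_000,
    method: str = "normal_approx",
    seed: int = 0,
) -> list[dict]:
    """Attained joint power of the sample-size procedure, design by design.

    Each design is sized with `sample_size`, then simulated at the
    resulting cohort total with binomial-prevalence sampling and the
    truth at the expected values.  The attained joint rate typically
    falls below the nominal per-component power because the joint test
    must clear both components.
    """
    if len(designs) < 1:
        raise ValueError("at least one design is required")
    out = []
    for i, design in enumerate(designs):
        size_res: SampleSizeResult = sample_size(design, method)
        scenario = TruthScenario(
            true_sensitivity=design.expected_sensitivity,
            true_specificity=design.expected_specificity,
            prevalence=design.prevalence,
            n_total=size_res.n_total,
            sampling="binomial_prevalence",
            seed=seed + i,
        )
        report = operating_characteristics(
            scenario, design.mac, design.alpha, n_replicates
        )
        out.append(
            {
                "design": design.to_dict(),
                "sample_size": size_res.to_dict(),
                "attained_power": report.rejection_rate,
                "mc_halfwidth": report.mc_halfwidth,
                "n_empty_margin": report.n_empty_margin,
            }
        )
    return out
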