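"""Plot-ready ROC-space geometry.

Everything here converts native (sensitivity, specificity) values to ROC
axes (x = 1 - specificity, y = sensitivity) at export time only, so no
intermediate code ever stores flipped coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .inference import JointTestResult
from .mac import LRRegion, MACriteria

__all__ = ["RegionGeometry", "export_region_geometry"]


@dataclass(frozen=True)
class RegionGeometry:
    """Target-region rectangle, optional LR boundary line and per-strategy
    confidence rectangles, all in ROC axes (1 - specificity, sensitivity).

    ``target_rectangle`` lists the four corners counter-clockwise from the
    lower-left; the region always contains the perfect-test corner (0, 1).
    The LR boundary is the line y = slope * x through the origin.  Each
    strategy contributes its point estimate and the corners of its
    one-sided rectangular confidence region [sens_lower, 1] x
    [spec_lower, 1] mapped into ROC axes.
    """

    target_rectangle: tuple[tuple[float, float], ...]
    lr_boundary: dict | None
    strategies: tuple[dict, ...]

    def to_dict(self) -> dict:
        return {
            "axes": {"x": "1 - specificity", "y": "sensitivity"},
            "target_rectangle": [list(c) for c in self.target_rectangle],
            "lr_boundary": self.lr_boundary,
            "strategies": [dict(s) for s in self.strategies],
        }


def _rectangle(sens_low: float, spec_low: float) -> tuple[tuple[float, float], ...]:
    x_max = 1.0 - spec_low
    return (
        (0.0, sens_low),
        (x_max, sens_low),
        (x_max, 1.0),
        (0.0, 1.0),
    )


def export_region_geometry(
    results: Sequence[JointTestResult] = (),
    mac: MACriteria | None = None,
    lr_region: LRRegion | None = None,
) -> RegionGeometry:
    """Build plot-ready geometry for the target region and study results.

    When ``mac`` is omitted it is taken from the first result; with no
    results and no MAC the target rectangle degenerates to the full ROC
    square (MAC 0/0).
    """
    if mac is None:
        mac = results[0].mac if len(results) else MACriteria(0.0, 0.0)
    target = _rectangle(mac.mac_sensitivity, mac.mac_specificity)
    lr = (
        {"slope": lr_region.min_positive_lr, "intercept": 0.0}
        if lr_region is not None
        else None
    )
    strategies = []
    for res in results:
        est = res.estimate
        strategies.append(
            {
                "label": res.label,
                "point": [1.0 - est.specificity, est.sensitivity],
                "confidence_rectangle": [
                    list(c) for c in _rectangle(est.sens_lower, est.spec_lower)
                ],
                "point_in_region": res.point_in_region,
                "confidence_region_in_region": res.confidence_region_in_region,
                "reject_null": res.reject_null,
            }
        )
    return RegionGeometry(
        target_rectangle=target,
        lr_boundary=lr,
        strategies=tuple(strategies),
    )
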