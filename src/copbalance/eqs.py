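"""Equilibrium Score (EQS) from anterior/posterior sway extremes.

The EQS is the single 0-100 balance summary a dynamic-posturography device
reports per test condition.  It compares the total anterior-posterior sway
range against a 12.5 degree theoretical stability limit in the sagittal
plane:

    EQS = 100 * (12.5 - (theta_max_ant - theta_max_post)) / 12.5

clamped below at 0 when the sway range exceeds the limit.  Posterior angles
are signed negative so the difference is the full range.  The score uses
only the two extreme samples of a trial — the very reduction that motivates
entropy-based features — and is kept here as the device baseline: it is
many-to-one (7/-5 and 6/-6 degrees score identically) and blind to
everything between the extremes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EquilibriumAngles", "equilibrium_score", "sway_extremes"]

STABILITY_LIMIT_DEG = 12.5


@dataclass(frozen=True)
class EquilibriumAngles:
    """Extreme sway angles of one trial, degrees (anterior positive)."""

    theta_max_ant: float
    theta_max_post: float
    stability_limit: float = STABILITY_LIMIT_DEG

    def __post_init__(self) -> None:
        if self.stability_limit <= 0:
            raise ValueError("stability limit must be positive")
        if self.theta_max_ant < self.theta_max_post:
            raise ValueError(
                f"anterior extreme {self.theta_max_ant} below posterior "
                f"extreme {self.theta_max_post}"
            )


def equilibrium_score(angles: EquilibriumAngles) -> float:
    """EQS in [0, 100]; 100 is no sway, 0 is sway at or beyond the limit."""
    sway_range = angles.theta_max_ant - angles.theta_max_post
    score = 100.0 * (angles.stability_limit - sway_range) / angles.stability_limit
    return max(score, 0.0)


def sway_extremes(theta_series: np.ndarray) -> EquilibriumAngles:
    """Extract (max, min) of a sway-angle series as the EQS extremes."""
    theta = np.asarray(theta_series, dtype=float)
    if theta.size == 0:
        raise ValueError("empty sway-angle series")
    return EquilibriumAngles(
        theta_max_ant=float(theta.max()), theta_max_post=float(theta.min())
    )
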