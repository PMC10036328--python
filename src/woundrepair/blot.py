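"""Western-blot densitometry: loading-control-normalized knockdown efficiency.

The knocked-down sample's target-band signal is rescaled by the ratio of
loading-control (ATPα) signals so control and knockdown lanes are
comparable, then expressed as percent reduction relative to the control
target band:

    normalized_target = kd_target × (control_loading / kd_loading)
    percent_knockdown = 100 × (1 − normalized_target / control_target)
"""

from __future__ import annotations

import dataclasses
import decimal
import warnings

__all__ = ["BlotMeasurement", "knockdown_efficiency"]


@dataclasses.dataclass
class BlotMeasurement:
    """Band signals (densitometry units) and derived knockdown efficiency."""

    control_loading: float
    control_target: float
    kd_loading: float
    kd_target: float
    normalized_target: float
    percent_knockdown: float  # unrounded, clipped to [0, 100]
    percent_rounded: int  # display value, half-up


def _round_half_up(value: float, digits: int = 0) -> float:
    q = decimal.Decimal(1).scaleb(-digits)
    return float(
        decimal.Decimal(repr(float(value))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


def knockdown_efficiency(
    control_loading: float,
    control_target: float,
    kd_loading: float,
    kd_target: float,
) -> BlotMeasurement:
    """Normalized target signal and percent knockdown from four band signals.

    All signals must be positive.  The displayed percentage is rounded
    half-up via an intermediate one-decimal step (85.4957 → 85.5 → 86),
    matching conventional densitometry reporting.  Values outside
    [0, 100]% are clipped with a warning.
    """
    for name, value in (
        ("control_loading", control_loading),
        ("control_target", control_target),
        ("kd_loading", kd_loading),
        ("kd_target", kd_target),
    ):
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value}")

    normalized = kd_target * (control_loading / kd_loading)
    percent = 100.0 * (1.0 - normalized / control_target)
    if percent < 0 or percent > 100:
        warnings.warn(
            f"knockdown {percent:.2f}% outside [0, 100]; clipping "
            "(normalized knockdown signal exceeds control, or is negative)",
            stacklevel=2,
        )
        percent = min(max(percent, 0.0), 100.0)
    rounded = int(_round_half_up(_round_half_up(percent, 1)))
    return BlotMeasurement(
        control_loading=control_loading,
        control_target=control_target,
        kd_loading=kd_loading,
        kd_target=kd_target,
        normalized_target=normalized,
        percent_knockdown=percent,
        percent_rounded=rounded,
    )
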