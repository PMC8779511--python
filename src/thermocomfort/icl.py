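"""Clothing insulation rate (Icl, in clo) from temperature differences.

The insulation of the worn clothing is estimated from the gradient between
mean skin temperature Ts and mean clothes-surface temperature Tc, relative
to the gradient between clothes and the operative temperature To:

    Icl = (Ts - Tc) / (0.155 * h * (Tc - To))

with all temperatures in °C, h the human heat-transfer coefficient in
W/(m² K) (8.6 by default), and 0.155 m² K/W the definition of one clo.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import PipelineConfig
from .thermal_regions import ThermalSummary

__all__ = ["CLO_FACTOR", "IllConditionedError", "IclResult", "compute_icl", "icl_from_summary"]

#: one clo in m^2 K / W
CLO_FACTOR = 0.155


class IllConditionedError(ValueError):
    """Raised when (Tc - To) is too small for a meaningful Icl estimate."""

    def __init__(self, tc: float, to: float, epsilon: float):
        super().__init__(
            f"ill-conditioned Icl estimate: |Tc - To| = {abs(tc - to):.4f} °C "
            f"is below epsilon = {epsilon} °C"
        )


@dataclass(frozen=True)
class IclResult:
    """An Icl estimate together with the summary it was computed from."""

    icl: float
    summary: ThermalSummary
    h: float
    window_frames: int
    partial_window: bool = False


def compute_icl(ts: float, tc: float, to: float, h: float = 8.6, epsilon: float = 0.1) -> float:
    """Clothing insulation rate in clo.

    A negative result (ts < tc) is returned as-is: it is a diagnostic for
    bad region localization, and clamping would hide the upstream error.

    Raises
    ------
    IllConditionedError
        When ``|tc - to| < epsilon`` (default 0.1 °C).
    """
    if h <= 0:
        raise ValueError(f"heat transfer coefficient must be positive, got {h}")
    if abs(tc - to) < epsilon:
        raise IllConditionedError(tc, to, epsilon)
    return (ts - tc) / (CLO_FACTOR * h * (tc - to))


def icl_from_summary(
    summary: ThermalSummary,
    config: PipelineConfig,
    window_frames: int,
    partial_window: bool = False,
) -> IclResult:
    """Apply :func:`compute_icl` to a window's thermal summary."""
    icl = compute_icl(
        summary.ts, summary.tc, summary.to,
        h=config.h_coefficient, epsilon=config.icl_epsilon,
    )
    return IclResult(
        icl=icl,
        summary=summary,
        h=config.h_coefficient,
        window_frames=window_frames,
        partial_window=partial_window,
    )
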