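"""Complexity-threshold derivation by inverting fitted deviation-vs-metric lines."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .regression import RegressionResult


@dataclass(frozen=True)
class ThresholdResult:
    metric_name: str
    parameter: str
    site_label: str
    dose_limit: float  # % deviation
    threshold: float  # metric value at which the fitted deviation hits the limit
    direction: str  # "above": plans are safe above the threshold; "below": under it


def derive_threshold(
    result: RegressionResult, dose_limit: float, slope_tol: float = 1e-12
) -> Optional[ThresholdResult]:
    """Invert ``deviation = slope * metric + intercept`` at ``dose_limit``.

    A negative slope (deviation shrinks as the metric grows, e.g. mean gap)
    means plans are safe *above* the threshold; a positive slope (e.g. the
    tongue-and-groove index) means safe *below* it.  Near-zero slopes yield
    no threshold (None).
    """
    if abs(result.slope) < slope_tol:
        return None
    threshold = (dose_limit - result.intercept) / result.slope
    return ThresholdResult(
        metric_name=result.metric_name,
        parameter=result.parameter,
        site_label=result.site_label,
        dose_limit=dose_limit,
        threshold=threshold,
        direction="above" if result.slope < 0 else "below",
    )
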