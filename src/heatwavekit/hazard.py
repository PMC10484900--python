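"""Relative heat-wave hazard index across a city cohort.

The index ranks cities by the projected intensification of heat waves:
how much longer the mean spell gets relative to the historical period
(``delta_duration``, days) and how far the spell intensity rises above
the city's effective threshold temperature (``excess_intensity``, °C).
Frequency is deliberately excluded — sub-spell counts are already
folded into duration.

Each component is min–max normalized across the cohort for one
period × scenario, so the score is a relative ranking within that
cohort, not an absolute hazard. The score is the equal-weight mean of
the two normalized components and lands in [0, 1]; classes cut at the
quartile boundaries 0.25 / 0.5 / 0.75.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError

CLASS_BOUNDS = (0.25, 0.5, 0.75)
CLASSES = ("low", "moderate", "high", "very_high")

DURATION_WEIGHT = 0.5
INTENSITY_WEIGHT = 0.5


@dataclass(frozen=True)
class HazardInput:
    """Per-city components feeding the index, for one period/scenario."""

    city_id: str
    delta_duration: float  # future minus historical mean duration, days
    excess_intensity: float  # intensity minus effective threshold, °C


@dataclass(frozen=True)
class HazardRecord:
    city_id: str
    period: str
    scenario: str
    delta_duration: float
    excess_intensity: float
    score: float  # ∈ [0, 1]
    hclass: str


def _minmax(values: np.ndarray) -> np.ndarray:
    """Min–max normalize to [0, 1]; a constant component maps to 0.5."""
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi == lo:
        return np.full(values.shape, 0.5)
    return (values - lo) / (hi - lo)


def classify(score: float) -> str:
    """Map a score in [0, 1] to its hazard class (boundaries round up)."""
    if not (0.0 <= score <= 1.0):
        raise ValidationError(f"score {score} outside [0, 1]")
    for bound, cls in zip(CLASS_BOUNDS, CLASSES):
        if score < bound:
            return cls
    return CLASSES[-1]


def hazard_scores(
    inputs: Sequence[HazardInput],
    period: str = "",
    scenario: str = "",
) -> list[HazardRecord]:
    """Score a city cohort for one period/scenario.

    Undefined components (cities with no heat-wave activity) should be
    passed as zero by the caller. The returned order matches the input.
    """
    if not inputs:
        raise ValidationError("hazard index needs at least one city")
    dd = np.array([c.delta_duration for c in inputs], dtype=float)
    ei = np.array([c.excess_intensity for c in inputs], dtype=float)
    if not (np.all(np.isfinite(dd)) and np.all(np.isfinite(ei))):
        raise ValidationError("hazard components must be finite")
    scores = DURATION_WEIGHT * _minmax(dd) + INTENSITY_WEIGHT * _minmax(ei)
    return [
        HazardRecord(
            city_id=c.city_id,
            period=period,
            scenario=scenario,
            delta_duration=float(dd[i]),
            excess_intensity=float(ei[i]),
            score=float(scores[i]),
            hclass=classify(float(scores[i])),
        )
        for i, c in enumerate(inputs)
    ]
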