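"""Estimated daily intakes and margins between points of departure and exposure."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExposureScenario",
    "RiskSummary",
    "compute_edi",
    "summarize_exposure",
    "margin_of_exposure",
]

log = logging.getLogger(__name__)

_CATEGORIES = ("food_supplement", "herbal_medicine")


@dataclass
class ExposureScenario:
    """One product-use scenario.

    ``content`` is mg active compound per g product, ``daily_amount`` in
    g product per day, ``body_weight`` in kg.
    """

    product: str
    category: str
    content: float
    daily_amount: float
    body_weight: float = 60.0

    def __post_init__(self) -> None:
        if self.category not in _CATEGORIES:
            raise ValueError(f"category must be one of {_CATEGORIES}")
        if self.content < 0 or self.daily_amount < 0:
            raise ValueError("content and daily amount must be non-negative")
        if self.body_weight <= 0:
            raise ValueError("body weight must be positive")


def compute_edi(scenario: ExposureScenario) -> float:
    """Estimated daily intake in mg/kg body weight per day."""
    return scenario.content * scenario.daily_amount / scenario.body_weight


@dataclass
class RiskSummary:
    """EDI distribution summary plus per-endpoint margins."""

    edis: np.ndarray
    geometric_mean: float
    p95: float
    range: tuple
    n_zero_excluded: int = 0
    margins: dict = field(default_factory=dict)  # endpoint -> BMDL/EDI fold


def summarize_exposure(scenarios) -> RiskSummary:
    """Geometric mean, empirical 95th percentile and range of the EDIs.

    Zero EDIs cannot enter the geometric mean and are excluded from it with
    a logged count; they still count for the percentile and range.
    """
    scenarios = list(scenarios)
    if not scenarios:
        raise ValueError("need at least one exposure scenario")
    edis = np.array([compute_edi(s) for s in scenarios])
    positive = edis[edis > 0]
    if positive.size == 0:
        raise ValueError("need at least one scenario with a positive EDI")
    n_zero = int(edis.size - positive.size)
    if n_zero:
        log.info("excluded %d zero EDIs from the geometric mean", n_zero)
    gm = float(np.exp(np.mean(np.log(positive))))
    p95 = float(np.percentile(edis, 95.0, method="linear"))
    return RiskSummary(
        edis=edis,
        geometric_mean=gm,
        p95=p95,
        range=(float(np.min(edis)), float(np.max(edis))),
        n_zero_excluded=n_zero,
    )


def margin_of_exposure(bmdl: float, edi: float) -> float:
    """Safety margin: point of departure divided by the daily intake (fold)."""
    if edi <= 0:
        raise ValueError("EDI must be positive")
    if bmdl < 0:
        raise ValueError("BMDL must be non-negative")
    return bmdl / edi
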