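"""Quantitative machinery for the modified Delphi consensus rounds.

Panelists rate candidate items on a 1-9 agreement scale.  Items go back for
re-rating when opinion is uncertain (median 4-6) or when the panel disagrees
(RAND/UCLA disagreement index above 1).  After the final round, retained
items (median >= 7) are grouped into themes and each theme's share of the
summed medians is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DelphiItem",
    "DisagreementResult",
    "disagreement_index",
    "select_for_rerating",
    "theme_contributions",
]

logger = logging.getLogger(__name__)

SCALE_MIDPOINT = 5.0  # centre of the 1-9 rating scale
IPRAS_INTERCEPT = 2.35  # RAND/UCLA appropriateness-method constants
IPRAS_SLOPE = 1.5


class DelphiError(ValueError):
    pass


@dataclass(frozen=True)
class DelphiItem:
    """One candidate statement with its panel ratings for a given round."""

    item_id: str
    text: str
    theme: str
    ratings: tuple[int, ...]
    round: int = 1

    def __post_init__(self) -> None:
        if not self.ratings:
            raise DelphiError(f"item {self.item_id!r} has no ratings")
        if any(not (1 <= r <= 9) or int(r) != r for r in self.ratings):
            raise DelphiError(f"item {self.item_id!r}: ratings must be integers 1-9")

    @property
    def median(self) -> float:
        return float(np.median(self.ratings))


@dataclass(frozen=True)
class DisagreementResult:
    """Interpercentile-range disagreement summary for one item."""

    ipr: float  # 70th - 30th percentile of ratings
    ipras: float  # symmetry-adjusted reference range
    di: float  # disagreement index = IPR / IPRAS; > 1 flags disagreement
    median: float


def disagreement_index(
    ratings: Sequence[int], percentile_method: str = "linear"
) -> DisagreementResult:
    """RAND/UCLA disagreement index of a set of 1-9 ratings.

    IPR is the 30th-70th interpercentile range; IPRAS = 2.35 + 1.5 * AI
    where the asymmetry index AI is the distance of the IPR's central point
    from the scale midpoint 5.  DI = IPR / IPRAS.  The percentile convention
    matters near the DI = 1 boundary, so it is switchable (any numpy
    percentile ``method``; default linear interpolation).
    """
    vals = np.asarray(ratings, dtype=float)
    if vals.size < 3:
        raise DelphiError(f"need >=3 ratings for a disagreement index (got {vals.size})")
    if np.any((vals < 1) | (vals > 9)):
        raise DelphiError("ratings must lie on the 1-9 scale")
    p30, p70 = np.percentile(vals, [30, 70], method=percentile_method)
    ipr = float(p70 - p30)
    iprcp = (p30 + p70) / 2.0
    ai = abs(SCALE_MIDPOINT - iprcp)
    ipras = IPRAS_INTERCEPT + IPRAS_SLOPE * ai
    return DisagreementResult(
        ipr=ipr,
        ipras=float(ipras),
        di=float(ipr / ipras),
        median=float(np.median(vals)),
    )


def select_for_rerating(
    items: Sequence[DelphiItem], percentile_method: str = "linear"
) -> list[tuple[DelphiItem, str]]:
    """Items needing another rating round, with the triggering rule.

    An item is selected when its median rating is 4 through 6 (uncertain
    opinion) or its disagreement index exceeds 1 (panel disagreement).
    Returns (item, reason) pairs; reason is "median", "disagreement" or
    "median+disagreement".
    """
    out: list[tuple[DelphiItem, str]] = []
    for item in items:
        reasons = []
        if 4 <= item.median <= 6:
            reasons.append("median")
        if len(item.ratings) >= 3:
            if disagreement_index(item.ratings, percentile_method).di > 1:
                reasons.append("disagreement")
        if reasons:
            out.append((item, "+".join(reasons)))
    return out


def theme_contributions(
    items: Sequence[DelphiItem], rating_floor: int = 7
) -> dict[str, tuple[float, float]]:
    """Per-theme sum of item medians and its percentage of the grand total.

    Items with median below ``rating_floor`` are dropped first (the final
    retained list used a floor of 7).  Percentages are rounded to 1 decimal.
    """
    kept = [it for it in items if it.median >= rating_floor]
    if not kept:
        logger.warning("theme_contributions: no items at or above the rating floor")
        return {}
    sums: dict[str, float] = {}
    for it in kept:
        sums[it.theme] = sums.get(it.theme, 0.0) + it.median
    total = sum(sums.values())
    return {
        theme: (s, round(s / total * 100.0, 1)) for theme, s in sums.items()
    }
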