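"""Bibliometric construct-validity analytics for importance scores.

If an instrument captures research-question importance, articles scoring
higher should preferentially appear in high-impact journals and accrue more
citations.  This module implements the unweighted 0-18 instrument sum, the
per-dimension Cramér's V association with journal-impact group, logistic
regression of journal group on score tertiles, and the log-citation
regression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .instrument import Instrument, Profile

__all__ = [
    "ArticleRecord",
    "AssociationResult",
    "unweighted_rqit_score",
    "cramers_v",
    "tertile_logistic",
    "citation_regression",
]

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class ArticleRecord:
    """One published trial, its instrument levels and bibliometric outcomes."""

    article_id: str
    levels: tuple[str, ...]
    journal_group: str  # "low" | "high"
    citation_count: int

    def __post_init__(self) -> None:
        if self.journal_group not in ("low", "high"):
            raise ValidationError("journal_group must be 'low' or 'high'")
        if self.citation_count < 0:
            raise ValidationError("citation_count must be >= 0")


@dataclass(frozen=True)
class AssociationResult:
    statistic: str
    value: float
    p_value: float
    detail: dict


def unweighted_rqit_score(
    levels: Sequence[str] | Profile, instrument: Instrument
) -> float:
    """Simple unweighted instrument sum on a 0-18 scale (6 dimensions).

    Each dimension's ordinal level index is mapped linearly onto [0, 3]
    (lowest level 0, highest 3; a 3-level dimension maps to {0, 1.5, 3}),
    then summed.  Generalizes to any dimension count as 3 per dimension.
    """
    if isinstance(levels, Profile):
        levels = levels.elements
    profile = Profile(levels)
    profile.validate(instrument)
    total = 0.0
    for dim, code in zip(instrument.dimensions, profile.elements):
        i = dim.level_codes.index(code)
        total += 3.0 * i / (len(dim.level_codes) - 1)
    return total


def cramers_v(table: Sequence[Sequence[float]] | np.ndarray) -> AssociationResult:
    """Cramér's V for an r x c contingency table.

    V = sqrt(chi2 / (n * min(r-1, c-1))), interpreted like a correlation
    coefficient.  The p-value is from the Pearson chi-square test, replaced
    by Fisher's exact test for 2x2 tables with any expected count below 5.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or np.any(obs < 0):
        raise ValidationError("contingency table must be 2-D with counts >= 0")
    n = obs.sum()
    if n <= 0:
        raise ValidationError("contingency table is empty")
    nonzero_rows = int((obs.sum(axis=1) > 0).sum())
    nonzero_cols = int((obs.sum(axis=0) > 0).sum())
    if nonzero_rows < 2 or nonzero_cols < 2:
        logger.warning("degenerate contingency table: V set to 0")
        return AssociationResult("Cramér's V", 0.0, 1.0, {"dof": 0, "n": int(n)})
    chi2, p, dof, expected = stats.chi2_contingency(obs, correction=False)
    r, c = obs.shape
    v = float(np.sqrt(chi2 / (n * min(r - 1, c - 1))))
    method = "chi-square"
    if np.any(expected < 5) and obs.shape == (2, 2):
        _, p = stats.fisher_exact(obs)
        method = "fisher"
    return AssociationResult(
        "Cramér's V", v, float(p), {"chi2": float(chi2), "dof": int(dof), "n": int(n), "p_method": method}
    )


def _tertile_codes(scores: np.ndarray) -> np.ndarray:
    """0/1/2 tertile membership with right-closed quantile cuts."""
    q1, q2 = np.quantile(scores, [1 / 3, 2 / 3])
    if q1 == q2:
        # heavy ties: shift the upper boundary to the next distinct value
        distinct = np.unique(scores)
        above = distinct[distinct > q2]
        if above.size == 0:
            raise ValidationError("scores too tied to form three tertiles")
        logger.warning("tertile boundaries shifted to nearest distinct value")
        q2 = above[0]
    t = np.where(scores <= q1, 0, np.where(scores <= q2, 1, 2))
    if len(np.unique(t)) < 3:
        raise ValidationError("could not form three non-empty tertiles")
    return t


def tertile_logistic(
    scores: Sequence[float], groups: Sequence
) -> AssociationResult:
    """Logistic regression of a binary outcome on score tertiles.

    Scores are cut at their empirical 1/3 and 2/3 quantiles; the model
    regresses the outcome (e.g. high vs low journal-impact group) on
    indicators for tertiles 2 and 3 (tertile 1 is the reference).  Reports
    odds ratios with 95% CIs, the model likelihood-ratio chi-square and
    Nagelkerke R².
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if g in (1, "high", True) else 0 for g in groups])
    if scores.shape[0] != y.shape[0]:
        raise ValidationError("scores and groups must have equal length")
    if np.unique(scores).size < 3:
        raise ValidationError("need >=3 distinct score values to form tertiles")
    t = _tertile_codes(scores)
    X = sm.add_constant(np.column_stack([(t == 1).astype(float), (t == 2).astype(float)]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X).fit(disp=0)
        null = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0)
    params = model.params[1:]
    conf = model.conf_int()[1:]
    ors = {
        f"tertile{j + 2}": {
            "or": float(np.exp(params[j])),
            "ci": (float(np.exp(conf[j][0])), float(np.exp(conf[j][1]))),
            "p": float(model.pvalues[j + 1]),
        }
        for j in range(2)
    }
    n = len(y)
    lr_chi2 = float(2 * (model.llf - null.llf))
    p = float(stats.chi2.sf(lr_chi2, 2))
    r2_cs = 1 - np.exp(2 * (null.llf - model.llf) / n)
    nagelkerke = float(r2_cs / (1 - np.exp(2 * null.llf / n)))
    return AssociationResult(
        "tertile logistic",
        ors["tertile3"]["or"],
        p,
        {"odds_ratios": ors, "model_chi2": lr_chi2, "df": 2, "nagelkerke_r2": nagelkerke,
         "tertile_counts": np.bincount(t, minlength=3).tolist()},
    )


def citation_regression(
    scores: Sequence[float], citations: Sequence[int], offset: float = 1.0
) -> AssociationResult:
    """Standardized slope of log citation count on the importance score.

    Citation counts are natural-log transformed (with ``offset`` added so
    zero counts are defined) and regressed on the score; the standardized
    coefficient is the slope after z-scoring both variables, i.e. the
    Pearson correlation for this simple regression.
    """
    x = np.asarray(scores, dtype=float)
    c = np.asarray(citations, dtype=float)
    if x.shape != c.shape:
        raise ValidationError("scores and citations must have equal length")
    if np.any(c < 0):
        raise ValidationError("citation counts must be >= 0")
    if np.std(x) == 0:
        raise ValidationError("scores are constant: slope undefined")
    ylog = np.log(c + offset)
    xz = (x - x.mean()) / x.std(ddof=1)
    if np.std(ylog) == 0:
        return AssociationResult("citation regression", 0.0, 1.0, {"n": len(x)})
    yz = (ylog - ylog.mean()) / ylog.std(ddof=1)
    model = sm.OLS(yz, sm.add_constant(xz)).fit()
    return AssociationResult(
        "citation regression",
        float(model.params[1]),
        float(model.pvalues[1]),
        {"n": len(x), "se": float(model.bse[1]), "r2": float(model.rsquared)},
    )
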