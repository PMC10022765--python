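"""Inter-rater reliability statistics for ordinal rating matrices.

Implements the statistics used to check that instrument levels can be
ordered consistently by raters: the two-way random-effects intraclass
correlation under absolute agreement (single and average measures, with
F-based confidence intervals), Gwet's chance-corrected AC2 coefficient,
modal percent agreement, and the ICC of randomly formed committees of
raters (whose averaged ratings are what the instrument is scored by in
practice).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RatingsMatrix",
    "AgreementEstimate",
    "icc_two_way",
    "gwet_ac2",
    "modal_agreement",
    "committee_icc",
]

logger = logging.getLogger(__name__)


class AgreementError(ValueError):
    pass


@dataclass(frozen=True)
class RatingsMatrix:
    """subjects x raters grid of 1-based ordinal categories (NaN = missing)."""

    data: np.ndarray
    n_categories: int

    def __init__(self, data, n_categories: int | None = None):
        arr = np.asarray(data, dtype=float)
        if arr.ndim != 2:
            raise AgreementError("ratings must be a 2-D subjects x raters grid")
        finite = arr[np.isfinite(arr)]
        if finite.size == 0:
            raise AgreementError("ratings matrix is empty")
        if np.any(finite < 1) or np.any(finite != np.round(finite)):
            raise AgreementError("ratings must be integer categories >= 1")
        K = int(n_categories) if n_categories is not None else int(finite.max())
        if K < 2:
            raise AgreementError("need at least 2 categories")
        if finite.max() > K:
            raise AgreementError("rating exceeds the stated category count")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "n_categories", K)

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_raters(self) -> int:
        return self.data.shape[1]

    def complete_raters(self) -> np.ndarray:
        """Columns restricted to raters with no missing ratings."""
        mask = np.isfinite(self.data).all(axis=0)
        return self.data[:, mask]


@dataclass(frozen=True)
class AgreementEstimate:
    statistic: str
    estimate: float
    ci: tuple[float, float] | None
    n_subjects: int
    n_raters: int


def _anova_mean_squares(y: np.ndarray) -> tuple[float, float, float]:
    """Two-way (subject x rater) ANOVA mean squares for a complete grid."""
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_two_way(
    ratings: RatingsMatrix | np.ndarray,
    unit: str = "single",
    confidence: float = 0.95,
) -> AgreementEstimate:
    """Two-way random-effects ICC under absolute agreement.

    ``unit='single'`` gives ICC(2,1), the reliability of one rater's
    categorization; ``unit='average'`` gives ICC(2,k) for the mean of the k
    raters.  Raters with any missing rating are dropped (listwise).  The CI
    uses the F-distribution method with Satterthwaite degrees of freedom.
    """
    if unit not in ("single", "average"):
        raise ValueError("unit must be 'single' or 'average'")
    if not isinstance(ratings, RatingsMatrix):
        ratings = RatingsMatrix(ratings)
    y = ratings.complete_raters()
    n, k = y.shape
    if n < 2 or k < 2:
        raise AgreementError(
            f"need >=2 subjects and >=2 complete raters (have {n} x {k})"
        )
    msr, msc, mse = _anova_mean_squares(y)
    denom_single = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom_single <= 0 or msr <= mse:
        if msr <= mse:
            logger.warning("between-subject variance not above error; ICC set to 0")
            est = 0.0
            icc1 = 0.0
        else:
            est = icc1 = 0.0
    else:
        icc1 = (msr - mse) / denom_single
        est = icc1 if unit == "single" else (msr - mse) / (msr + (msc - mse) / n)

    # F-based CI for ICC(A,1); Spearman-Brown maps bounds to the average case
    alpha = 1 - confidence
    r = max(icc1, 0.0)
    a = k * r / (n * (1 - r)) if r < 1 else np.inf
    b = 1 + k * r * (n - 1) / (n * (1 - r)) if r < 1 else np.inf
    if math.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
        if unit == "average":
            lower = k * lower / (1 + (k - 1) * lower)
            upper = k * upper / (1 + (k - 1) * upper)
        ci = (float(min(lower, est)), float(min(max(upper, est), 1.0)))
    else:
        ci = (float("nan"), float("nan"))
    name = "ICC(2,1)" if unit == "single" else f"ICC(2,{k})"
    return AgreementEstimate(name, float(est), ci, n, k)


def _weight_matrix(K: int, weights: str) -> np.ndarray:
    idx = np.arange(K)
    if weights == "nominal":
        return np.eye(K)
    if weights == "quadratic":
        return 1.0 - (idx[:, None] - idx[None, :]) ** 2 / (K - 1) ** 2
    raise ValueError("weights must be 'nominal' or 'quadratic'")


def _ac2_from_counts(counts: np.ndarray, W: np.ndarray) -> float:
    """AC2 point estimate from a subjects x categories count matrix."""
    K = counts.shape[1]
    r_i = counts.sum(axis=1)
    use = r_i >= 2
    counts = counts[use]
    r_i = r_i[use]
    n = counts.shape[0]
    if n == 0:
        raise AgreementError("no subject is rated by >=2 raters")
    pi_k = (counts / r_i[:, None]).mean(axis=0)
    weighted = counts @ W.T  # r*_ik = sum_l w_kl r_il
    pa_i = ((counts * (weighted - 1)).sum(axis=1)) / (r_i * (r_i - 1))
    pa = pa_i.mean()
    tw = W.sum()
    pe = tw / (K * (K - 1)) * float(pi_k @ (1 - pi_k))
    if pe >= 1.0:
        return 1.0
    return float((pa - pe) / (1 - pe))


def gwet_ac2(
    ratings: RatingsMatrix | np.ndarray,
    weights: str = "quadratic",
    confidence: float = 0.95,
) -> AgreementEstimate:
    """Gwet's AC2 chance-corrected weighted agreement among multiple raters.

    Robust to the prevalence paradoxes that depress kappa-type indices.
    With nominal (identity) weights this reduces to Gwet's AC1.  The
    variance is estimated by a subject-level jackknife; missing ratings are
    handled pairwise (subjects keep whichever raters rated them).
    """
    if not isinstance(ratings, RatingsMatrix):
        ratings = RatingsMatrix(ratings)
    K = ratings.n_categories
    W = _weight_matrix(K, weights)
    counts = np.zeros((ratings.n_subjects, K))
    for k in range(K):
        counts[:, k] = np.nansum(ratings.data == k + 1, axis=1)
    r_i = counts.sum(axis=1)
    excluded = int((r_i < 2).sum())
    if excluded:
        logger.info("gwet_ac2: excluded %d subject(s) with <2 raters", excluded)
    counts = counts[r_i >= 2]
    n = counts.shape[0]
    if n < 1:
        raise AgreementError("no subject is rated by >=2 raters")
    est = _ac2_from_counts(counts, W)
    if n >= 2:
        jack = np.array(
            [_ac2_from_counts(np.delete(counts, i, axis=0), W) for i in range(n)]
        )
        var = (n - 1) / n * np.sum((jack - jack.mean()) ** 2)
        half = stats.t.ppf(1 - (1 - confidence) / 2, n - 1) * math.sqrt(var)
        ci = (float(est - half), float(min(est + half, 1.0)))
    else:
        ci = None
    name = "AC1" if weights == "nominal" else "AC2"
    return AgreementEstimate(name, est, ci, n, int(np.max(r_i)))


def modal_agreement(ratings: RatingsMatrix | np.ndarray) -> float:
    """Mean percent agreement based on each subject's modal category.

    Per subject the agreement is the share of its raters choosing the most
    frequent category (ties use the tied maximum count); the statistic is
    the mean over subjects, on a 0-100 scale.
    """
    if not isinstance(ratings, RatingsMatrix):
        ratings = RatingsMatrix(ratings)
    pcts = []
    for row in ratings.data:
        vals = row[np.isfinite(row)]
        if vals.size == 0:
            continue
        _, counts = np.unique(vals, return_counts=True)
        pcts.append(counts.max() / vals.size * 100.0)
    if not pcts:
        raise AgreementError("no rated subjects")
    return float(np.mean(pcts))


def committee_icc(
    ratings: RatingsMatrix | np.ndarray,
    committee_sizes: Sequence[int],
    seed: int = 0,
) -> AgreementEstimate:
    """ICC(2,1) of committee-average ratings.

    Raters with complete data are randomly partitioned (reproducibly from
    ``seed``) into committees of the given sizes; each committee's mean
    rating per subject forms a subjects x committees matrix whose
    single-measure ICC estimates the reliability of scoring by committee
    consensus.  No CI is reported for this resampled statistic.
    """
    if not isinstance(ratings, RatingsMatrix):
        ratings = RatingsMatrix(ratings)
    y = ratings.complete_raters()
    n, k = y.shape
    sizes = list(committee_sizes)
    if any(s < 1 for s in sizes):
        raise AgreementError("committee sizes must be >= 1")
    if sum(sizes) != k:
        raise AgreementError(
            f"committee sizes sum to {sum(sizes)} but there are {k} complete raters"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(k)
    means = np.empty((n, len(sizes)))
    pos = 0
    for j, s in enumerate(sizes):
        cols = order[pos : pos + s]
        means[:, j] = y[:, cols].mean(axis=1)
        pos += s
    msr, msc, mse = _anova_mean_squares(means)
    kc = len(sizes)
    denom = msr + (kc - 1) * mse + kc * (msc - mse) / n
    est = 0.0 if denom <= 0 or msr <= mse else (msr - mse) / denom
    return AgreementEstimate("committee ICC(2,1)", float(est), None, n, kc)
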