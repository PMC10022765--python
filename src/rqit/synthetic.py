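"""Synthetic data generators for every analysis stage.

Three generators emulate the data the instrument-development studies
collected: Thurstonian best-worst responses with known element utilities,
ordinal rating matrices with a controllable true intraclass correlation,
and article records with controllable score-outcome associations.  Every
generator is byte-deterministic given its seed.

The best-worst defaults reproduce the published survey's conditions: 41
respondents, a ~0.6% single-ended answer rate, a common respondent SEM of 1
(the latent scale unit), and true latent utilities equal to the published
0-1000 table scaled by 0.006 — a signal-to-noise level at which a survey of
roughly 3000 comparisons yields element standard errors of about 5-8 points
on the reporting scale, matching the published table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .agreement import RatingsMatrix
from .design import ChoiceTask
from .fit import BWResponse
from .instrument import Instrument, load_default_table
from .validation import ArticleRecord

__all__ = [
    "SimulationConfig",
    "default_true_utilities",
    "simulate_bws_responses",
    "simulate_ratings",
    "simulate_articles",
]

LATENT_SCALE = 0.006  # latent utility per published score point (SEM = 1)


def default_true_utilities() -> dict[str, float]:
    """Published element utilities mapped onto the latent Thurstone scale."""
    table = load_default_table()
    return {e: table.utility(e) * LATENT_SCALE for e in table.instrument.element_codes}


@dataclass
class SimulationConfig:
    """Ground-truth parameters for the synthetic generators.

    Best-worst fields: ``n_respondents``, ``true_utilities`` (element code ->
    latent utility; default the published table on the latent scale),
    ``dispersion`` (common SEM), ``dispersion_sigma`` (log-normal sigma of
    per-respondent SEMs; 0 = common SEM) and ``single_ended_rate``.

    Ratings fields: ``n_raters`` x ``n_subjects`` grids on ``n_categories``
    categories from a latent subject effect (SD ``subject_sd``) plus rater
    noise (SD ``noise_sd``); the implied true ICC is
    ``subject_sd^2 / (subject_sd^2 + noise_sd^2)``.

    Article fields: ``n_articles`` profiles with journal group assigned by a
    logistic model on weighted-score tertiles (``tertile2_log_odds``,
    ``tertile3_log_odds``) and citations drawn log-normally with a true
    standardized score effect ``citation_effect``.
    """

    seed: int = 0
    # --- best-worst survey ---
    n_respondents: int = 41
    true_utilities: Mapping[str, float] | None = None
    dispersion: float = 1.0
    dispersion_sigma: float = 0.0
    single_ended_rate: float = 0.006
    # --- rating matrices ---
    n_raters: int = 30
    n_subjects: int = 14
    n_categories: int = 4
    subject_sd: float = 1.0
    noise_sd: float = 1.0 / math.sqrt(3.0)  # true ICC 0.75
    # --- article records ---
    n_articles: int = 200
    tertile2_log_odds: float = math.log(3.0)
    tertile3_log_odds: float = math.log(6.0)
    citation_effect: float = 0.33
    citation_log_mean: float = 4.0
    stratified: bool = False

    def __post_init__(self) -> None:
        for name in ("dispersion", "subject_sd", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.single_ended_rate <= 1:
            raise ValueError("single_ended_rate must be in [0, 1]")

    @property
    def true_icc(self) -> float:
        v = self.subject_sd**2
        return v / (v + self.noise_sd**2)


def simulate_bws_responses(
    config: SimulationConfig, design: Sequence[ChoiceTask]
) -> list[BWResponse]:
    """Draw best-worst answers from the Thurstone generative model.

    Each respondent perceives every option's utility (sum of its two
    elements' true utilities) with independent normal error of SD ``s_r``
    and reports the perceived maximum as best and minimum as worst.  A
    fraction ``single_ended_rate`` of answers drop one of the two ends.
    """
    truth = dict(config.true_utilities or default_true_utilities())
    for t in design:
        for opt in t.options:
            for e in opt:
                if e not in truth:
                    raise KeyError(f"true utilities missing element {e!r}")
    rng = np.random.default_rng(config.seed)
    option_u = np.array(
        [[truth[a] + truth[b] for a, b in t.options] for t in design]
    )  # tasks x 3
    responses: list[BWResponse] = []
    for r in range(config.n_respondents):
        rid = f"R{r + 1:03d}"
        if config.dispersion_sigma > 0:
            s_r = config.dispersion * math.exp(
                rng.normal(0.0, config.dispersion_sigma)
            )
        else:
            s_r = config.dispersion
        noise = rng.normal(0.0, s_r, size=option_u.shape)
        perceived = option_u + noise
        best = perceived.argmax(axis=1) + 1
        worst = perceived.argmin(axis=1) + 1
        for i, task in enumerate(design):
            b, w = int(best[i]), int(worst[i])
            if config.single_ended_rate and rng.random() < config.single_ended_rate:
                if rng.random() < 0.5:
                    responses.append(BWResponse(rid, task.task_id, b, None))
                else:
                    responses.append(BWResponse(rid, task.task_id, None, w))
            else:
                responses.append(BWResponse(rid, task.task_id, b, w))
    return responses


def simulate_ratings(config: SimulationConfig) -> tuple[RatingsMatrix, dict]:
    """Draw a subjects x raters ordinal grid with known true ICC.

    Latent value = subject effect + rater noise, discretized into
    ``n_categories`` by equal-probability cutpoints of the marginal latent
    distribution.  Returns the matrix and metadata including the closed-form
    latent true ICC.
    """
    rng = np.random.default_rng(config.seed)
    n, k, K = config.n_subjects, config.n_raters, config.n_categories
    subject = rng.normal(0.0, config.subject_sd, size=(n, 1))
    noise = rng.normal(0.0, config.noise_sd, size=(n, k))
    latent = subject + noise
    total_sd = math.sqrt(config.subject_sd**2 + config.noise_sd**2)
    cuts = norm.ppf(np.arange(1, K) / K, scale=total_sd)
    grid = np.digitize(latent, cuts) + 1  # 1..K
    matrix = RatingsMatrix(grid.astype(float), n_categories=K)
    meta = {
        "true_icc": config.true_icc,
        "cutpoints": cuts.tolist(),
        "subject_sd": config.subject_sd,
        "noise_sd": config.noise_sd,
    }
    return matrix, meta


def simulate_articles(
    config: SimulationConfig, instrument: Instrument | None = None
) -> list[ArticleRecord]:
    """Draw article records with controllable score-outcome associations.

    Profiles are uniform per dimension; the weighted score (published
    utilities) determines the journal group through a logistic model on
    score tertiles, and citation counts are log-normal with a true
    standardized score effect.  ``stratified`` mode balances the two journal
    groups exactly (n/2 each), emulating selection of a fixed number of
    articles per journal stratum.
    """
    if config.n_articles < 30:
        raise ValueError("need n_articles >= 30")
    table = load_default_table()
    if instrument is None:
        instrument = table.instrument
    rng = np.random.default_rng(config.seed)
    target = config.n_articles

    def batch(size: int) -> list[tuple[tuple[str, ...], float, str, int]]:
        rows = []
        profiles = []
        for _ in range(size):
            profiles.append(
                tuple(
                    d.level_codes[rng.integers(len(d.level_codes))]
                    for d in instrument.dimensions
                )
            )
        scores = np.array(
            [sum(table.utility(e) for e in p) for p in profiles]
        )
        t = np.searchsorted(np.quantile(scores, [1 / 3, 2 / 3]), scores, side="left")
        eta = np.where(
            t == 2, config.tertile3_log_odds, np.where(t == 1, config.tertile2_log_odds, 0.0)
        )
        # centre the linear predictor so groups are roughly balanced
        eta = eta - eta.mean()
        p_high = 1.0 / (1.0 + np.exp(-eta))
        group = np.where(rng.random(size) < p_high, "high", "low")
        z = (scores - scores.mean()) / (scores.std(ddof=0) or 1.0)
        eff = config.citation_effect
        slope = eff / math.sqrt(max(1.0 - eff**2, 1e-12))
        logc = config.citation_log_mean + slope * z + rng.normal(0.0, 1.0, size)
        cites = np.maximum(np.round(np.exp(logc)), 0).astype(int)
        for i in range(size):
            rows.append((profiles[i], float(scores[i]), str(group[i]), int(cites[i])))
        return rows

    if config.stratified:
        half = target // 2
        picked: dict[str, list] = {"low": [], "high": []}
        while len(picked["low"]) < half or len(picked["high"]) < half:
            for row in batch(target):
                if len(picked[row[2]]) < half:
                    picked[row[2]].append(row)
        rows = picked["low"] + picked["high"]
    else:
        rows = batch(target)
    return [
        ArticleRecord(
            article_id=f"P{i + 1:04d}",
            levels=rows[i][0],
            journal_group=rows[i][2],
            citation_count=rows[i][3],
        )
        for i in range(len(rows))
    ]
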