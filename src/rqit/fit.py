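"""Thurstone paired-comparison fitting for best-worst scaling responses.

A best-worst answer on a three-option task ranks the chosen best above the
other two and the other two above the chosen worst, yielding three implied
paired comparisons (two if only one end was answered).  Under Thurstone's
model each respondent perceives an option's utility with additive normal
error, so the probability that option i beats option j is
``Phi((U_i - U_j) / (s * sqrt(2)))`` where ``U`` sums the option's two
element utilities and ``s`` is the respondent's standard error of
measurement (SEM).

Three model variants are fitted by maximum likelihood:

* **Model 1** — each respondent has their own SEM ``s_r`` (normalized to
  geometric mean 1, which fixes the latent scale);
* **Model 2a** — a single common SEM, utilities identified by anchoring the
  lowest level of each dimension at 0;
* **Model 2b** — the same model reparameterized with within-dimension
  utilities summing to 0, which makes all elements' standard errors directly
  comparable (standard errors come from the inverse observed information).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .design import ChoiceTask
from .instrument import Instrument, UtilityTable

__all__ = [
    "BWResponse",
    "PairedComparison",
    "FitResult",
    "expand_comparisons",
    "negative_log_likelihood",
    "fit",
    "rescale",
]

GRAD_TOL = 1e-6  # convergence: inf-norm of the mean-NLL gradient
RIDGE = 1e-4  # separation penalty weight on sum(u^2)


class FitError(RuntimeError):
    """Fitting failed or inputs are inconsistent."""


@dataclass(frozen=True)
class BWResponse:
    """One respondent's answer to one choice-task (1-based option indices)."""

    respondent_id: str
    task_id: str
    best: int | None
    worst: int | None

    def __post_init__(self) -> None:
        if self.best is None and self.worst is None:
            raise ValueError(
                f"response ({self.respondent_id},{self.task_id}): "
                "at least one of best/worst must be given"
            )
        for v in (self.best, self.worst):
            if v is not None and v not in (1, 2, 3):
                raise ValueError(f"option index {v} out of range 1-3")
        if self.best is not None and self.best == self.worst:
            raise ValueError(
                f"response ({self.respondent_id},{self.task_id}): best == worst"
            )


@dataclass(frozen=True)
class PairedComparison:
    """winner option preferred over loser option (element-code pairs)."""

    respondent_id: str
    winner: tuple[str, str]
    loser: tuple[str, str]

    def __post_init__(self) -> None:
        if self.winner == self.loser:
            raise ValueError("winner and loser must differ")


def expand_comparisons(
    responses: Sequence[BWResponse], design: Sequence[ChoiceTask]
) -> list[PairedComparison]:
    """Convert best-worst answers into their implied paired comparisons.

    A complete answer (best and worst of three) implies the full rank order
    best > middle > worst, i.e. three comparisons; a best-only answer implies
    best over each other option, a worst-only answer each other option over
    worst.  The output size is ``3*n_complete + 2*n_partial``.
    """
    tasks = {t.task_id: t for t in design}
    out: list[PairedComparison] = []
    for r in responses:
        if r.task_id not in tasks:
            raise KeyError(f"response references unknown task_id {r.task_id!r}")
        opts = tasks[r.task_id].options
        idx = {1, 2, 3}
        if r.best is not None and r.worst is not None:
            (mid,) = idx - {r.best, r.worst}
            pairs = [(r.best, mid), (r.best, r.worst), (mid, r.worst)]
        elif r.best is not None:
            others = sorted(idx - {r.best})
            pairs = [(r.best, o) for o in others]
        else:
            others = sorted(idx - {r.worst})
            pairs = [(o, r.worst) for o in others]
        for w, l in pairs:
            out.append(
                PairedComparison(
                    respondent_id=r.respondent_id,
                    winner=opts[w - 1],
                    loser=opts[l - 1],
                )
            )
    return out


# ---------------------------------------------------------------------------
# likelihood internals


class _Data:
    """Comparisons compiled to index arrays for vectorized likelihood work."""

    def __init__(self, comparisons: Sequence[PairedComparison]):
        if not comparisons:
            raise FitError("no comparisons to fit")
        elements = sorted({e for c in comparisons for e in (*c.winner, *c.loser)})
        self.elements = elements
        self.e_index = {e: i for i, e in enumerate(elements)}
        respondents = sorted({c.respondent_id for c in comparisons})
        self.respondents = respondents
        r_index = {r: i for i, r in enumerate(respondents)}
        n = len(comparisons)
        m = len(elements)
        # signed incidence: +1 for winner elements, -1 for loser elements
        X = np.zeros((n, m))
        for i, c in enumerate(comparisons):
            for e in c.winner:
                X[i, self.e_index[e]] += 1.0
            for e in c.loser:
                X[i, self.e_index[e]] -= 1.0
        self.X = X
        self.resp = np.array([r_index[c.respondent_id] for c in comparisons])
        self.n = n
        # dimension blocks from the element-code convention (letter + index)
        dims: dict[str, list[int]] = {}
        for e in elements:
            dims.setdefault(e[0], []).append(self.e_index[e])
        self.dim_blocks = [np.array(v) for v in dims.values()]

    def separated_elements(self) -> list[str]:
        """Elements appearing only on the winning or only on the losing side."""
        wins = (self.X > 0).sum(axis=0)
        losses = (self.X < 0).sum(axis=0)
        out = []
        for e, i in self.e_index.items():
            if (wins[i] == 0) != (losses[i] == 0):
                out.append(e)
        return out


def _nll_core(u, log_s, data: _Data, denom_scale: float, ridge: float):
    """Mean NLL, gradient wrt u, and per-respondent grad wrt log s."""
    s = np.exp(log_s)[data.resp]
    denom = s * denom_scale
    z = (data.X @ u) / denom
    # log Phi and its derivative, numerically stable in the far tail
    logphi = norm.logcdf(z)
    ratio = np.exp(norm.logpdf(z) - logphi)  # phi/Phi
    nll = -logphi.sum() / data.n
    gu = -(data.X.T @ (ratio / denom)) / data.n
    g_logs_i = (ratio * z) / data.n  # per comparison
    g_logs = np.bincount(data.resp, weights=g_logs_i, minlength=len(data.respondents))
    if ridge:
        nll += ridge * float(u @ u)
        gu += 2.0 * ridge * u
    return nll, gu, g_logs


def negative_log_likelihood(
    utilities: Mapping[str, float],
    dispersions: float | Mapping[str, float],
    comparisons: Sequence[PairedComparison],
    model: str = "2b",
    option_error_correlation: float = 0.0,
) -> float:
    """Total negative log-likelihood of a set of paired comparisons.

    ``dispersions`` is a single SEM (Models 2a/2b) or a respondent->SEM
    mapping (Model 1).  Each comparison contributes
    ``-log Phi((U_w - U_l) / (s_r * sqrt(2 (1 - c))))`` where ``c`` is the
    optional correlation between the two options' perception errors.
    """
    data = _Data(comparisons)
    u = np.array([float(utilities[e]) for e in data.elements])
    if isinstance(dispersions, Mapping):
        s = np.array([float(dispersions[r]) for r in data.respondents])
    else:
        s = np.full(len(data.respondents), float(dispersions))
    if np.any(s <= 0):
        raise ValueError("dispersions must be > 0")
    if not -1.0 < option_error_correlation < 1.0:
        raise ValueError("option error correlation must lie in (-1, 1)")
    denom_scale = np.sqrt(2.0 * (1.0 - option_error_correlation))
    nll, _, _ = _nll_core(u, np.log(s), data, denom_scale, ridge=0.0)
    return float(nll * data.n)


def _basis(data: _Data, model: str) -> np.ndarray:
    """Map free utility parameters to element utilities (columns of B)."""
    m = len(data.elements)
    cols = []
    for block in data.dim_blocks:
        L = len(block)
        if model == "2b":
            # sum-to-zero: last level carries minus the sum of the others
            for j in range(L - 1):
                col = np.zeros(m)
                col[block[j]] = 1.0
                col[block[-1]] = -1.0
                cols.append(col)
        else:  # "2a" and "1": anchor the lowest level at 0
            for j in range(1, L):
                col = np.zeros(m)
                col[block[j]] = 1.0
                cols.append(col)
    return np.column_stack(cols)


@dataclass
class FitResult:
    """Maximum-likelihood estimates from a Thurstone paired-comparison fit."""

    model: str
    element_order: list[str]
    utilities: dict[str, float]
    dispersions: float | dict[str, float]
    cov_utilities: np.ndarray  # covariance of element-utility estimates
    log_likelihood: float
    n_comparisons: int
    converged: bool
    n_iter: int
    grad_norm: float
    separation: list[str] = field(default_factory=list)

    @property
    def standard_errors(self) -> dict[str, float]:
        d = np.sqrt(np.clip(np.diag(self.cov_utilities), 0, None))
        return dict(zip(self.element_order, d))

    @property
    def correlations(self) -> np.ndarray:
        d = np.sqrt(np.clip(np.diag(self.cov_utilities), 1e-300, None))
        return self.cov_utilities / np.outer(d, d)


def fit(
    comparisons: Sequence[PairedComparison],
    model: str = "2b",
    seed: int = 0,
    option_error_correlation: float = 0.0,
    n_starts: int = 3,
) -> FitResult:
    """Fit Thurstone's paired-comparison model by maximum likelihood.

    Quasi-Newton optimization with analytic gradient and ``n_starts``
    seeded starts; standard errors and correlations of the utility estimates
    come from the inverse observed information at the optimum (computed in
    the model's own parameterization and mapped to element space).
    """
    if model not in ("1", "2a", "2b"):
        raise ValueError(f"unknown model tag {model!r}")
    data = _Data(comparisons)
    separated = data.separated_elements()
    ridge = RIDGE if separated else 0.0
    denom_scale = np.sqrt(2.0 * (1.0 - option_error_correlation))
    B = _basis(data, model)
    k = B.shape[1]
    R = len(data.respondents)
    per_respondent = model == "1"
    n_disp = R if per_respondent else 0  # Model 2: SEM fixed at 1 (scale unit)

    def unpack(x):
        theta, t = x[:k], x[k:]
        u = B @ theta
        if per_respondent:
            log_s = t - t.mean()  # geometric-mean-1 normalization
        else:
            log_s = np.zeros(R)
        return u, log_s

    def objective(x):
        u, log_s = unpack(x)
        nll, gu, g_logs = _nll_core(u, log_s, data, denom_scale, ridge)
        g_theta = B.T @ gu
        if per_respondent:
            g_t = g_logs - g_logs.sum() / R
            return nll, np.concatenate([g_theta, g_t])
        return nll, g_theta

    rng = np.random.default_rng(seed)
    best = None
    total_iter = 0
    for start in range(n_starts):
        x0 = np.zeros(k + n_disp)
        if start > 0:
            x0[:k] = rng.normal(scale=0.1, size=k)
        res = optimize.minimize(
            objective, x0, jac=True, method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-9},
        )
        total_iter += res.nit
        if best is None or res.fun < best.fun:
            best = res
    x = best.x
    gnorm = float(np.max(np.abs(objective(x)[1])))
    if gnorm > GRAD_TOL:  # polish with full BFGS
        res = optimize.minimize(
            objective, x, jac=True, method="BFGS",
            options={"maxiter": 500, "gtol": 1e-8},
        )
        total_iter += res.nit
        if res.fun <= best.fun:
            x = res.x
            gnorm = float(np.max(np.abs(objective(x)[1])))
    converged = gnorm <= GRAD_TOL
    if not converged and not separated:
        raise FitError(f"optimizer did not converge (gradient norm {gnorm:.2e})")

    u, log_s = unpack(x)
    nll_mean, _, _ = _nll_core(u, log_s, data, denom_scale, ridge=0.0)
    # observed information of the *total* NLL, by central differences of the
    # analytic gradient; mapped to element space through the basis
    H = _num_hessian(objective, x) * data.n
    cov_x = np.linalg.pinv(H)
    cov_u = B @ cov_x[:k, :k] @ B.T
    dispersions: float | dict[str, float]
    if per_respondent:
        dispersions = dict(zip(data.respondents, np.exp(log_s)))
    else:
        dispersions = 1.0
    return FitResult(
        model=model,
        element_order=list(data.elements),
        utilities=dict(zip(data.elements, u)),
        dispersions=dispersions,
        cov_utilities=cov_u,
        log_likelihood=float(-nll_mean * data.n),
        n_comparisons=data.n,
        converged=converged,
        n_iter=total_iter,
        grad_norm=gnorm,
        separation=separated,
    )


def _num_hessian(objective, x, eps: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian from an analytic-gradient objective."""
    p = len(x)
    H = np.zeros((p, p))
    for j in range(p):
        step = np.zeros(p)
        step[j] = eps
        gp = objective(x + step)[1]
        gm = objective(x - step)[1]
        H[:, j] = (gp - gm) / (2 * eps)
    return (H + H.T) / 2


def rescale(fit_result: FitResult, instrument: Instrument) -> UtilityTable:
    """Rescale fitted latent utilities to the 0-1000 reporting scale.

    Per dimension the lowest level's utility is translated to zero, then all
    utilities are multiplied by the constant that makes the maximal profile
    (top level of every dimension) sum to 1000.  Standard errors scale by the
    same constant (translation leaves them unchanged); correlations are
    untouched.
    """
    if not fit_result.converged:
        raise FitError("cannot rescale: fit did not converge")
    u = dict(fit_result.utilities)
    missing = [e for e in instrument.element_codes if e not in u]
    if missing:
        raise FitError(f"fit lacks utilities for elements: {missing}")
    shifted: dict[str, float] = {}
    for dim in instrument.dimensions:
        low = u[dim.level_codes[0]]
        for c in dim.level_codes:
            shifted[c] = u[c] - low
    top = sum(shifted[d.level_codes[-1]] for d in instrument.dimensions)
    if top <= 0:
        raise FitError(f"degenerate fit: maximal profile utility {top:.3g} <= 0")
    k = 1000.0 / top
    codes = list(instrument.element_codes)
    order = {e: i for i, e in enumerate(fit_result.element_order)}
    idx = [order[c] for c in codes]
    cov = fit_result.cov_utilities[np.ix_(idx, idx)] * k * k
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    d = np.where(se > 0, se, 1.0)
    rho = np.clip(cov / np.outer(d, d), -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return UtilityTable(
        instrument=instrument,
        utilities={c: shifted[c] * k for c in codes},
        standard_errors=dict(zip(codes, se)),
        correlations=rho,
        scale=(0.0, 1000.0),
    )
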