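"""Reliability statistics: ICC, Gwet's AC2, modal agreement, committee ICC."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rqit.agreement import (
    AgreementError,
    RatingsMatrix,
    committee_icc,
    gwet_ac2,
    icc_two_way,
    modal_agreement,
)
from rqit.synthetic import SimulationConfig, simulate_ratings


def anova_icc_oracle(y: np.ndarray, unit: str = "single") -> float:
    """ICC(2,1)/(2,k) from a two-way ANOVA fitted by statsmodels OLS
    (independent route: model-based mean squares, not direct sums)."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    n, k = y.shape
    df = pd.DataFrame({
        "rating": y.ravel(),
        "subject": np.repeat(np.arange(n), k).astype(str),
        "rater": np.tile(np.arange(k), n).astype(str),
    })
    tab = sm.stats.anova_lm(ols("rating ~ C(subject) + C(rater)", df).fit(), typ=2)
    msr = tab.loc["C(subject)", "sum_sq"] / tab.loc["C(subject)", "df"]
    msc = tab.loc["C(rater)", "sum_sq"] / tab.loc["C(rater)", "df"]
    mse = tab.loc["Residual", "sum_sq"] / tab.loc["Residual", "df"]
    if unit == "single":
        return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return (msr - mse) / (msr + (msc - mse) / n)


def pairwise_ac2_oracle(y: np.ndarray, K: int, weights: str) -> float:
    """Gwet's AC2 via explicit enumeration of all rater pairs per subject."""
    if weights == "quadratic":
        w = lambda a, b: 1 - (a - b) ** 2 / (K - 1) ** 2
    else:
        w = lambda a, b: float(a == b)
    pa_parts, pi = [], np.zeros(K)
    n = 0
    for row in y:
        vals = row[np.isfinite(row)].astype(int)
        if len(vals) < 2:
            continue
        n += 1
        pairs = list(itertools.permutations(range(len(vals)), 2))
        pa_parts.append(np.mean([w(vals[i], vals[j]) for i, j in pairs]))
        for k_ in range(1, K + 1):
            pi[k_ - 1] += np.mean(vals == k_)
    pi /= n
    pa = np.mean(pa_parts)
    tw = sum(w(a, b) for a in range(1, K + 1) for b in range(1, K + 1))
    pe = tw / (K * (K - 1)) * float(pi @ (1 - pi))
    return (pa - pe) / (1 - pe)


class TestICC:
    def test_perfect_agreement(self):
        y = np.tile(np.array([[1], [2], [3], [4]]), (1, 5))
        assert icc_two_way(y).estimate == pytest.approx(1.0)

    def test_matches_anova_oracle_on_random_matrices(self, rng):
        """Direct mean-squares ICC equals the model-based oracle to 1e-6."""
        for _ in range(50):
            n, k = rng.integers(4, 15), rng.integers(3, 10)
            y = rng.integers(1, 6, size=(n, k)).astype(float)
            if np.all(y == y[0, 0]) or icc_two_way(y).estimate == 0.0:
                continue
            for unit in ("single", "average"):
                assert icc_two_way(y, unit).estimate == pytest.approx(
                    anova_icc_oracle(y, unit), abs=1e-6)

    def test_matches_pingouin(self, rng):
        """Cross-check point estimates and CIs against pingouin's ICC2/ICC2k."""
        pingouin = pytest.importorskip("pingouin")
        y = rng.integers(1, 6, size=(14, 8)).astype(float)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(14), 8),
            "rater": np.tile(np.arange(8), 14),
            "rating": y.ravel(),
        })
        res = pingouin.intraclass_corr(df, "subject", "rater", "rating").set_index("Type")
        single = icc_two_way(y, "single")
        average = icc_two_way(y, "average")
        assert single.estimate == pytest.approx(res.loc["ICC(A,1)", "ICC"], abs=1e-9)
        assert average.estimate == pytest.approx(res.loc["ICC(A,k)", "ICC"], abs=1e-9)
        # pingouin prints CI bounds rounded to 2 decimals
        assert single.ci[0] == pytest.approx(res.loc["ICC(A,1)", "CI95"][0], abs=6e-3)
        assert single.ci[1] == pytest.approx(res.loc["ICC(A,1)", "CI95"][1], abs=6e-3)

    def test_average_at_least_single(self, rng):
        y = rng.integers(1, 5, size=(10, 6)).astype(float)
        s, a = icc_two_way(y, "single"), icc_two_way(y, "average")
        if s.estimate > 0:
            assert a.estimate >= s.estimate

    def test_invariances(self, rng):
        y = rng.integers(1, 6, size=(12, 7)).astype(float)
        base = icc_two_way(y).estimate
        perm = y[rng.permutation(12)]
        assert icc_two_way(perm).estimate == pytest.approx(base)
        assert icc_two_way(y + 3).estimate == pytest.approx(base)

    def test_listwise_rater_deletion(self):
        y = np.array([[1, 2, np.nan], [2, 3, 1], [3, 4, 2], [4, 5, 2]])
        est = icc_two_way(RatingsMatrix(y))
        assert est.n_raters == 2  # third rater dropped

    def test_zero_between_subject_variance_gives_zero(self):
        y = np.array([[2, 3], [2, 3], [2, 3]], dtype=float)
        assert icc_two_way(y).estimate == 0.0

    def test_too_small_rejected(self):
        with pytest.raises(AgreementError):
            icc_two_way(np.array([[1.0, 2.0]]))


class TestGwetAC2:
    def test_unanimous_agreement_is_one(self):
        y = np.tile(np.array([[1], [3], [2], [4]]), (1, 6)).astype(float)
        assert gwet_ac2(RatingsMatrix(y, 4)).estimate == pytest.approx(1.0)

    def test_toy_grid_matches_pairwise_oracle(self):
        y = np.array([[1, 1, 2], [2, 2, 2], [3, 4, 4], [1, 2, 1]], dtype=float)
        for weights in ("quadratic", "nominal"):
            got = gwet_ac2(RatingsMatrix(y, 4), weights).estimate
            assert got == pytest.approx(pairwise_ac2_oracle(y, 4, weights), abs=1e-12)

    def test_random_grids_match_oracle(self, rng):
        for _ in range(50):
            n, k = rng.integers(3, 12), rng.integers(2, 8)
            K = int(rng.integers(2, 6))
            y = rng.integers(1, K + 1, size=(n, k)).astype(float)
            got = gwet_ac2(RatingsMatrix(y, K), "quadratic").estimate
            assert got == pytest.approx(pairwise_ac2_oracle(y, K, "quadratic"), abs=1e-6)

    def test_binary_scale_equals_ac1(self, rng):
        """With K=2, quadratic weights collapse to the identity, so AC2 = AC1."""
        y = rng.integers(1, 3, size=(20, 5)).astype(float)
        q = gwet_ac2(RatingsMatrix(y, 2), "quadratic").estimate
        n = gwet_ac2(RatingsMatrix(y, 2), "nominal").estimate
        assert q == pytest.approx(n, abs=1e-12)

    def test_chance_only_agreement_near_zero(self, rng):
        y = rng.integers(1, 5, size=(1000, 4)).astype(float)
        est = gwet_ac2(RatingsMatrix(y, 4))
        se = (est.ci[1] - est.estimate) / 1.96 if est.ci else 0.05
        assert abs(est.estimate) < 3 * max(se, 0.01)

    def test_missing_handled_pairwise(self):
        y = np.array([[1, 1, np.nan], [2, np.nan, np.nan], [3, 3, 3]], dtype=float)
        est = gwet_ac2(RatingsMatrix(y, 3))
        assert est.n_subjects == 2  # the singleton-rated subject is excluded


class TestModalAgreement:
    def test_unanimous(self):
        y = np.tile(np.array([[2], [3]]), (1, 4)).astype(float)
        assert modal_agreement(y) == 100.0

    def test_printed_example_row(self):
        assert modal_agreement(np.array([[1, 1, 2, 3]], dtype=float)) == 50.0

    def test_random_grid_matches_counting_oracle(self, rng):
        y = rng.integers(1, 5, size=(14, 32)).astype(float)
        expected = np.mean([
            max(np.bincount(row.astype(int))) / len(row) * 100 for row in y
        ])
        assert modal_agreement(y) == pytest.approx(expected)


class TestCommitteeICC:
    def test_published_sizing(self, rng):
        y = rng.integers(1, 5, size=(14, 26)).astype(float)
        est = committee_icc(y, [5, 5, 5, 5, 6], seed=3)
        assert est.n_subjects == 14 and est.n_raters == 5
        assert est.ci is None

    def test_singleton_committees_reduce_to_individual_icc(self, rng):
        y = rng.integers(1, 5, size=(10, 6)).astype(float)
        est = committee_icc(y, [1] * 6, seed=0)
        assert est.estimate == pytest.approx(icc_two_way(y).estimate, abs=1e-12)

    def test_averaging_raises_reliability_under_noise(self):
        """With noisy raters, committee averages agree better than individuals
        in nearly every replicate."""
        wins = 0
        for s in range(100):
            cfg = SimulationConfig(seed=s, n_raters=30, n_subjects=14,
                                   subject_sd=0.5, noise_sd=1.0)
            m, _ = simulate_ratings(cfg)
            ind = icc_two_way(m).estimate
            com = committee_icc(m, [5] * 6, seed=s).estimate
            wins += com > ind
        assert wins >= 95

    def test_infeasible_sizes_rejected(self, rng):
        y = rng.integers(1, 5, size=(5, 6)).astype(float)
        with pytest.raises(AgreementError, match="sum"):
            committee_icc(y, [3, 4], seed=0)
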