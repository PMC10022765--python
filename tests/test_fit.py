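"""Best-worst expansion and Thurstone paired-comparison estimation."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import norm

from rqit.design import ChoiceTask
from rqit.fit import (
    BWResponse,
    FitResult,
    PairedComparison,
    expand_comparisons,
    fit,
    negative_log_likelihood,
    rescale,
)
from rqit.instrument import Profile, score_profile
from rqit.synthetic import SimulationConfig, simulate_bws_responses

from conftest import make_instrument


@pytest.fixture
def toy_task():
    return ChoiceTask(
        task_id="T001",
        dimension_pair=("A", "B"),
        options=(("A1", "B3"), ("A2", "B2"), ("A3", "B1")),
    )


class TestExpansion:
    def test_complete_answer_implies_full_rank_order(self, toy_task):
        resp = [BWResponse("r1", "T001", best=1, worst=3)]
        comps = expand_comparisons(resp, [toy_task])
        got = {(c.winner, c.loser) for c in comps}
        opts = toy_task.options
        assert got == {(opts[0], opts[1]), (opts[0], opts[2]), (opts[1], opts[2])}

    @pytest.mark.parametrize("best,worst,n_expected", [
        (1, 3, 3), (2, 1, 3), (1, None, 2), (None, 2, 2),
    ])
    def test_comparison_counts(self, toy_task, best, worst, n_expected):
        comps = expand_comparisons([BWResponse("r", "T001", best, worst)], [toy_task])
        assert len(comps) == n_expected

    def test_single_ended_directions(self, toy_task):
        best_only = expand_comparisons([BWResponse("r", "T001", 2, None)], [toy_task])
        assert all(c.winner == toy_task.options[1] for c in best_only)
        worst_only = expand_comparisons([BWResponse("r", "T001", None, 2)], [toy_task])
        assert all(c.loser == toy_task.options[1] for c in worst_only)

    def test_empty_input(self, toy_task):
        assert expand_comparisons([], [toy_task]) == []

    def test_expansion_arithmetic(self, toy_task, rng):
        """|comparisons| = 3*n_both + 2*n_single for any response mix."""
        for _ in range(10):
            n_both, n_single = rng.integers(0, 50), rng.integers(0, 50)
            responses = [BWResponse(f"r{i}", "T001", 1, 2) for i in range(n_both)]
            responses += [BWResponse(f"s{i}", "T001", 3, None) for i in range(n_single)]
            assert len(expand_comparisons(responses, [toy_task])) == 3 * n_both + 2 * n_single

    def test_best_equals_worst_rejected(self):
        with pytest.raises(ValueError, match="best == worst"):
            BWResponse("r", "T001", 2, 2)

    def test_unknown_task_rejected(self, toy_task):
        with pytest.raises(KeyError, match="T999"):
            expand_comparisons([BWResponse("r", "T999", 1, 2)], [toy_task])


class TestLikelihood:
    def test_equal_utilities_contribute_log_half(self):
        comp = PairedComparison("r", ("A1", "B2"), ("A2", "B1"))
        u = {"A1": 1.0, "A2": 2.0, "B1": 3.0, "B2": 4.0}  # sums equal: 5 vs 5
        nll = negative_log_likelihood(u, 1.0, [comp])
        assert nll == pytest.approx(-math.log(0.5))

    def test_within_dimension_shift_invariance(self, tasks):
        """Adding a constant to every element of one dimension leaves the
        likelihood unchanged (per-task dimension pairing cancels it)."""
        cfg = SimulationConfig(seed=5, n_respondents=10)
        comps = expand_comparisons(simulate_bws_responses(cfg, tasks), tasks)
        rng = np.random.default_rng(0)
        u = {e: float(rng.normal()) for e in
             {x for c in comps for x in (*c.winner, *c.loser)}}
        base = negative_log_likelihood(u, 1.0, comps)
        for dim_letter, const in [("A", 2.5), ("C", -1.33), ("E", 17.0)]:
            shifted = {k: v + const if k[0] == dim_letter else v for k, v in u.items()}
            assert negative_log_likelihood(shifted, 1.0, comps) == pytest.approx(
                base, rel=1e-9)

    def test_matches_per_term_oracle(self, toy_task, rng):
        """Total NLL equals a term-by-term direct evaluation."""
        comps = expand_comparisons(
            [BWResponse(f"r{i}", "T001", int(rng.integers(1, 4)), None) for i in range(30)],
            [toy_task],
        )
        u = {e: float(rng.normal()) for e in ("A1", "A2", "A3", "B1", "B2", "B3")}
        s = {f"r{i}": float(rng.uniform(0.5, 2.0)) for i in range(30)}
        expected = 0.0
        for c in comps:
            du = sum(u[e] for e in c.winner) - sum(u[e] for e in c.loser)
            expected += -math.log(norm.cdf(du / (s[c.respondent_id] * math.sqrt(2))))
        got = negative_log_likelihood(u, s, comps, model="1")
        assert got == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_dispersion_rejected(self, toy_task):
        comp = expand_comparisons([BWResponse("r", "T001", 1, 3)], [toy_task])
        with pytest.raises(ValueError, match="dispersion"):
            negative_log_likelihood(dict.fromkeys(
                ("A1", "A2", "A3", "B1", "B2", "B3"), 0.0), 0.0, comp)


class TestFit:
    def test_balanced_comparisons_give_zero_difference(self):
        """Equal wins both ways between two options -> zero utility difference."""
        a, b = ("A1", "B2"), ("A2", "B1")
        comps = [PairedComparison("r", a, b)] * 10 + [PairedComparison("r", b, a)] * 10
        res = fit(comps, model="2b", seed=0)
        du = sum(res.utilities[e] for e in a) - sum(res.utilities[e] for e in b)
        assert du == pytest.approx(0.0, abs=1e-6)

    def test_sum_to_zero_constraint_holds(self, tasks):
        cfg = SimulationConfig(seed=2, n_respondents=15)
        comps = expand_comparisons(simulate_bws_responses(cfg, tasks), tasks)
        res = fit(comps, model="2b", seed=0)
        for letter in "ABCDE":
            total = sum(v for e, v in res.utilities.items() if e[0] == letter)
            assert total == pytest.approx(0.0, abs=1e-9)

    def test_covariance_symmetric_psd(self, tasks):
        cfg = SimulationConfig(seed=2, n_respondents=15)
        comps = expand_comparisons(simulate_bws_responses(cfg, tasks), tasks)
        res = fit(comps, model="2b", seed=0)
        cov = res.cov_utilities
        assert np.allclose(cov, cov.T, atol=1e-10)
        assert np.linalg.eigvalsh(cov).min() > -1e-10

    def test_fitted_preference_probabilities_transitive(self, tasks):
        """P(i>j) > 1/2 and P(j>k) > 1/2 imply P(i>k) > 1/2."""
        cfg = SimulationConfig(seed=4, n_respondents=15)
        comps = expand_comparisons(simulate_bws_responses(cfg, tasks), tasks)
        res = fit(comps, model="2b", seed=0)
        opts = list({o for t in tasks for o in t.options})[:12]
        util = {o: res.utilities[o[0]] + res.utilities[o[1]] for o in opts}
        p = lambda i, j: norm.cdf((util[i] - util[j]) / math.sqrt(2))
        for i, j, k in itertools.permutations(opts[:6], 3):
            if p(i, j) > 0.5 and p(j, k) > 0.5:
                assert p(i, k) > 0.5

    def test_separation_engages_ridge_and_flags(self):
        a, b = ("A1", "B2"), ("A2", "B1")
        comps = [PairedComparison(f"r{i}", a, b) for i in range(20)]
        res = fit(comps, model="2b", seed=0)
        assert set(res.separation) == {"A1", "A2", "B1", "B2"}
        assert all(np.isfinite(v) for v in res.utilities.values())


class TestRescale:
    def _fit_result(self, utilities, elements=None, model="2b"):
        elements = elements or sorted(utilities)
        m = len(elements)
        return FitResult(
            model=model, element_order=list(elements), utilities=dict(utilities),
            dispersions=1.0, cov_utilities=np.zeros((m, m)), log_likelihood=0.0,
            n_comparisons=1, converged=True, n_iter=1, grad_norm=0.0,
        )

    def test_two_step_transform_forced_values(self):
        inst = make_instrument([3, 3])
        u = {"A1": -1, "A2": 0, "A3": 1, "B1": -1, "B2": 0, "B3": 1}
        table = rescale(self._fit_result(u), inst)
        for letter in "AB":
            assert [table.utility(f"{letter}{i}") for i in (1, 2, 3)] == [0, 250, 500]
        assert score_profile(Profile(["A3", "B3"]), table).value == 1000

    def test_anchors_after_rescaling(self, tasks, instrument):
        cfg = SimulationConfig(seed=6, n_respondents=15)
        comps = expand_comparisons(simulate_bws_responses(cfg, tasks), tasks)
        table = rescale(fit(comps, model="2b", seed=0), instrument)
        assert score_profile(table.min_profile(), table).value == pytest.approx(0.0, abs=1e-9)
        assert score_profile(table.max_profile(), table).value == pytest.approx(1000.0, abs=1e-9)

    def test_se_scales_with_k_translation_free(self):
        inst = make_instrument([2, 2])
        u = {"A1": 0.0, "A2": 1.0, "B1": 0.0, "B2": 1.0}
        elements = ["A1", "A2", "B1", "B2"]
        fr = self._fit_result(u, elements)
        fr.cov_utilities = np.eye(4) * 0.01  # SE 0.1 per element
        table = rescale(fr, inst)
        # k = 1000 / 2: utilities 0/500 per dimension, SEs 0.1 * 500
        assert table.utility("A2") == pytest.approx(500.0)
        assert table.se("A2") == pytest.approx(50.0)
        assert table.se("A1") == pytest.approx(50.0)  # translation leaves SE alone

    def test_degenerate_fit_rejected(self):
        inst = make_instrument([2])
        fr = self._fit_result({"A1": 1.0, "A2": 1.0}, ["A1", "A2"])
        with pytest.raises(RuntimeError, match="degenerate"):
            rescale(fr, inst)
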