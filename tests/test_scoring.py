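"""Pattern EAPs, the summed-score recursion, and translation tables."""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import spearmanr

import mnrm
from mnrm import (
    ItemParameters,
    MNRMModel,
    ResponseMatrix,
    ScoringFunctionSet,
    build_grid,
    compare_scores,
    pattern_eap,
    score_by_sum,
    summed_score_likelihood,
    translation_table,
)
from mnrm.errors import ValidationError
from mnrm.estimation import _pattern_logL


class TestPatternEAP:
    def test_zero_information_returns_prior(self):
        items = [ItemParameters(a=[0.0], c=np.zeros(4)) for _ in range(3)]
        s = ScoringFunctionSet(["d"], [np.arange(4.0).reshape(-1, 1)] * 3)
        model = MNRMModel(items=items, scoring=s)
        grid = build_grid(49, -6, 6, R=np.eye(1))
        resp = ResponseMatrix.from_patterns(["012"], K=4)
        out = pattern_eap(model, grid, resp)
        assert out.eap[0, 0] == pytest.approx(0.0, abs=1e-3)
        assert out.sd[0, 0] == pytest.approx(1.0, abs=1e-3)

    def test_matches_exhaustive_posterior_oracle(self, wx):
        # brute-force posterior means over the same grid, straight from the
        # category response function
        patterns = ["006", "352", "660"]
        resp = ResponseMatrix.from_patterns(patterns, K=7)
        out = pattern_eap(wx.model, wx.grid, resp)
        for i, pat in enumerate(patterns):
            post = wx.grid.weights.copy()
            for j, ch in enumerate(pat):
                probs = [
                    mnrm.category_response_prob(
                        wx.model.items[j], wx.scoring.for_item(j), x
                    )[int(ch)]
                    for x in wx.grid.nodes
                ]
                post *= np.array(probs)
            post /= post.sum()
            for d in range(2):
                want = post @ wx.grid.nodes[:, d]
                assert out.eap[i, d] == pytest.approx(want, abs=1e-8)

    def test_identical_patterns_identical_scores(self, wx):
        resp = ResponseMatrix.from_patterns(["135", "135"], K=7)
        out = pattern_eap(wx.model, wx.grid, resp)
        np.testing.assert_array_equal(out.eap[0], out.eap[1])
        np.testing.assert_array_equal(out.sd[0], out.sd[1])

    def test_all_missing_flagged_with_prior(self, wx):
        resp = ResponseMatrix.from_patterns(["...", "024"], K=7)
        grid = build_grid(49, -6, 6, R=wx.model.R)
        out = pattern_eap(wx.model, grid, resp)
        assert out.all_missing[0] and not out.all_missing[1]
        np.testing.assert_allclose(out.eap[0], 0.0, atol=1e-3)
        np.testing.assert_allclose(out.sd[0], 1.0, atol=1e-3)

    def test_posterior_sd_never_exceeds_prior_sd(self, wx):
        patterns = ["".join(map(str, p))
                    for p in itertools.product([0, 3, 6], repeat=3)]
        resp = ResponseMatrix.from_patterns(patterns, K=7)
        grid = build_grid(49, -6, 6, R=wx.model.R)
        out = pattern_eap(wx.model, grid, resp)
        prior_sd = np.sqrt(grid.weights @ grid.nodes**2)
        assert np.all(out.sd <= prior_sd + 1e-10)


class TestSummedScoreLikelihood:
    def test_final_step_reference_values(self, wx, wx_order):
        ssl = summed_score_likelihood(wx.model, wx.scoring, "ERS", wx.grid)
        np.testing.assert_array_equal(ssl.scores, [0, 1, 2, 3])
        for v, want in wx.expected["final_likelihood"].items():
            np.testing.assert_allclose(ssl.L[v][wx_order], want, atol=0.0025)

    def test_intermediate_step_reference_values(self, wx, wx_order):
        two = MNRMModel(
            items=wx.model.items[:2],
            scoring=ScoringFunctionSet(wx.scoring.labels, wx.scoring.matrices[:2]),
            R=wx.model.R,
        )
        ssl = summed_score_likelihood(two, two.scoring, "ERS", wx.grid)
        for v, want in wx.expected["two_item_likelihood"].items():
            np.testing.assert_allclose(ssl.L[v][wx_order], want, atol=0.0025)

    def test_single_item_equals_collapsed_response(self, wx):
        one = MNRMModel(
            items=wx.model.items[:1],
            scoring=ScoringFunctionSet(wx.scoring.labels, wx.scoring.matrices[:1]),
            R=wx.model.R,
        )
        ssl = summed_score_likelihood(one, one.scoring, "ERS", wx.grid)
        for q in range(wx.grid.n_nodes):
            values, probs = mnrm.collapsed_response_prob(
                wx.model.items[0], wx.scoring.for_item(0), 1, wx.grid.nodes[q]
            )
            np.testing.assert_allclose(ssl.L[:, q], probs, atol=1e-14)

    def test_recursion_equals_exhaustive_enumeration(self, wx):
        # all 343 patterns of the three 7-category items, grouped by ERS sum
        ssl = summed_score_likelihood(wx.model, wx.scoring, "ERS", wx.grid)
        brute = np.zeros_like(ssl.L)
        for pat in itertools.product(range(7), repeat=3):
            v = sum(int(k in (0, 6)) for k in pat)
            p = np.ones(wx.grid.n_nodes)
            for j, k in enumerate(pat):
                p *= [
                    mnrm.category_response_prob(
                        wx.model.items[j], wx.scoring.for_item(j), x
                    )[k]
                    for x in wx.grid.nodes
                ]
            brute[v] += p
        np.testing.assert_allclose(ssl.L, brute, atol=1e-12)

    def test_total_probability_at_every_node(self, wx):
        ssl = summed_score_likelihood(wx.model, wx.scoring, "QOL", wx.grid)
        np.testing.assert_allclose(ssl.L.sum(axis=0), 1.0, atol=1e-10)

    def test_non_integer_codes_supported(self, wx):
        # half-point style codes: recursion keys on exact attainable sums
        mats = [m.copy() for m in wx.scoring.matrices]
        for m in mats:
            m[:, 1] = m[:, 1] * 0.5
        s_half = ScoringFunctionSet(wx.scoring.labels, mats)
        ssl = summed_score_likelihood(wx.model, s_half, "ERS", wx.grid)
        np.testing.assert_array_equal(ssl.scores, [0.0, 0.5, 1.0, 1.5])
        np.testing.assert_allclose(ssl.L.sum(axis=0), 1.0, atol=1e-10)


class TestTranslationTable:
    def test_reference_table_and_kernel(self, wx):
        table = translation_table(wx.model, wx.scoring, "ERS", wx.grid)
        np.testing.assert_array_equal(table.eta_nodes, [-2, 0, 2])
        for v, want in wx.expected["kernel"].items():
            np.testing.assert_allclose(table.kernel[v], want, atol=0.0025)
        for v, (p, eap, var) in wx.expected["translation"].items():
            assert table.p[v] == pytest.approx(p, abs=0.0025)
            assert table.eap[v] == pytest.approx(eap, abs=0.0025)
            assert table.var[v] == pytest.approx(var, abs=0.0025)

    def test_marginal_probabilities_sum_to_one(self, wx):
        table = translation_table(wx.model, wx.scoring, "ERS", wx.grid)
        assert table.p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_law_of_total_expectation(self, wx):
        table = translation_table(wx.model, wx.scoring, "ERS", wx.grid)
        assert table.p @ table.eap == pytest.approx(0.0, abs=1e-2)

    def test_uninformative_style_dimension_scores_zero(self):
        # zero ERS slopes everywhere: E(eta | v) = prior mean for every v
        items = [
            ItemParameters(a=[0.8, 0.0], c=[0, 1.0, 1.5, 1.2, 0.7, 0.3, 0.1])
            for _ in range(3)
        ]
        s = ScoringFunctionSet.from_templates(["QOL", "ERS"], ["trait", "ers"], [7] * 3)
        model = MNRMModel(items=items, scoring=s)
        grid = build_grid(31, -5, 5, R=np.eye(2))
        table = translation_table(model, s, "ERS", grid)
        np.testing.assert_allclose(table.eap, 0.0, atol=1e-8)

    def test_lookup_and_unattainable_score(self, wx):
        table = translation_table(wx.model, wx.scoring, "ERS", wx.grid)
        eap, sd = score_by_sum(table, 2)
        assert eap == pytest.approx(table.eap[2])
        assert sd == pytest.approx(np.sqrt(table.var[2]))
        with pytest.raises(ValidationError):
            score_by_sum(table, 4)
        with pytest.raises(ValidationError):
            score_by_sum(table, -1)


class TestCompareScores:
    def test_sum_score_eap_rank_equals_sum_score(self, wx):
        patterns = ["".join(map(str, p))
                    for p in itertools.product(range(7), repeat=3)][::7]
        resp = ResponseMatrix.from_patterns(patterns, K=7)
        grid = build_grid(31, -5, 5, R=wx.model.R)
        report = compare_scores(resp, wx.model, wx.scoring, grid)
        sub = report.scores.dropna()
        rho = spearmanr(sub["v_ERS"], sub["ssEAP_ERS"]).statistic
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_correlation_matrices_well_formed(self, small_study):
        grid = build_grid(21, -5, 5, R=small_study.model.R)
        report = compare_scores(
            small_study.responses, small_study.model, small_study.scoring, grid
        )
        for mat in (report.pearson, report.spearman):
            vals = mat.to_numpy()
            np.testing.assert_allclose(vals, vals.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(vals), 1.0, atol=1e-12)
            assert np.all(np.isfinite(vals))

    def test_equal_slope_pcm_eap_is_rank_equivalent_to_sum_score(self):
        # a unidimensional partial-credit model with slopes constrained
        # equal: the sum score is sufficient, so pattern EAPs are a strictly
        # monotone function of it (rank correlation 1 after tie rounding)
        rng = np.random.default_rng(3)
        items = [
            ItemParameters(
                a=[0.8], c=np.concatenate([[0.0], np.sort(rng.normal(1.2, 0.8, 4))])
            )
            for _ in range(6)
        ]
        s = ScoringFunctionSet.from_templates(["trait"], ["trait"], [5] * 6)
        truth = MNRMModel(items=items, scoring=s)
        design = mnrm.SimulationDesign(
            n_persons=400, n_items=6, n_categories=5,
            labels=("trait",), templates=("trait",),
            slope_range=((0.3, 1.0),), seed=11,
        )
        lat = mnrm.draw_latent(design)
        resp = mnrm.simulate_responses(truth, lat, 12)
        model, summary = mnrm.fit_em(resp, s, equal_slopes=True, tol=1e-6)
        assert summary.converged
        slopes = {round(float(it.a[0]), 10) for it in model.items}
        assert len(slopes) == 1
        grid = build_grid(49, -6, 6, R=model.R)
        eap = pattern_eap(model, grid, resp).eap[:, 0]
        v = mnrm.sum_score(resp, s, 0).scores
        rho = spearmanr(np.round(eap, 10), v).statistic
        assert rho == pytest.approx(1.0, abs=1e-9)
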