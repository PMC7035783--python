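import numpy as np
import pytest
from scipy.spatial.distance import jensenshannon

from lincpipe.model import ExpressionMatrix
from lincpipe.tissue_specificity import (
    ScoreError,
    SpecificityResult,
    call_specific,
    js_divergence,
    score_histogram,
    score_matrix,
    specificity_score,
)


class TestJsDivergence:
    def test_identity(self):
        assert js_divergence([0.3, 0.7], [0.3, 0.7]) == 0.0

    def test_disjoint_supports_reach_one(self):
        assert js_divergence([1.0, 0.0], [0.0, 1.0]) == 1.0

    def test_half_vs_unit(self):
        assert js_divergence([0.5, 0.5], [1.0, 0.0]) == pytest.approx(
            0.31128, abs=1e-5)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(2, 12)
            p = rng.dirichlet(np.ones(n))
            q = rng.dirichlet(np.ones(n))
            d = js_divergence(p, q)
            assert d == pytest.approx(js_divergence(q, p), abs=1e-12)
            assert -1e-12 <= d <= 1 + 1e-12

    def test_agrees_with_scipy(self):
        """Independent cross-check: scipy returns sqrt(JSD) in the given base."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(2, 12)
            p = rng.dirichlet(np.ones(n))
            q = rng.dirichlet(np.ones(n))
            assert np.sqrt(js_divergence(p, q)) == pytest.approx(
                float(jensenshannon(p, q, base=2)), abs=1e-9)

    @pytest.mark.parametrize("p,q", [
        ([0.5, 0.5], [0.3, 0.3, 0.4]),        # length mismatch
        ([0.5, 0.6], [0.5, 0.5]),             # not normalized
        ([1.5, -0.5], [0.5, 0.5]),            # negative entry
        ([1.0], [1.0]),                       # too short
    ])
    def test_bad_input_rejected(self, p, q):
        with pytest.raises(ScoreError):
            js_divergence(p, q)


class TestSpecificityScore:
    def test_single_condition_scores_exactly_one(self):
        res = specificity_score([0.0, 7.3, 0.0, 0.0],
                                ["a", "b", "c", "d"])
        assert res.js_score == 1.0
        assert res.argmax_condition == "b"

    def test_uniform_two_conditions(self):
        res = specificity_score([5.0, 5.0])
        assert res.js_score == pytest.approx(1 - np.sqrt(0.31128), abs=1e-5)

    def test_scaling_invariance(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            e = rng.uniform(0, 50, size=8)
            e[0] = 1.0  # keep at least one positive entry
            for c in (1e-3, 2.0, 1e4):
                assert specificity_score(c * e).js_score == pytest.approx(
                    specificity_score(e).js_score, abs=1e-12)

    def test_score_one_iff_single_support(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            e = np.zeros(6)
            k = rng.integers(1, 7)
            idx = rng.choice(6, size=k, replace=False)
            e[idx] = rng.uniform(1, 10, size=k)
            score = specificity_score(e).js_score
            assert (score == 1.0) == (k == 1)

    def test_uniform_is_minimum_over_full_support(self):
        """Spreading expression evenly gives the lowest score (n <= 10)."""
        rng = np.random.default_rng(4)
        for n in range(2, 11):
            uniform_score = specificity_score(np.ones(n)).js_score
            for _ in range(50):
                e = rng.uniform(0.05, 10, size=n)
                assert specificity_score(e).js_score >= uniform_score - 1e-12

    def test_all_zero_vector_not_scorable(self):
        with pytest.raises(ScoreError):
            specificity_score([0.0, 0.0, 0.0])

    def test_tie_broken_by_declared_order(self):
        res = specificity_score([3.0, 3.0], ["first", "second"])
        assert res.argmax_condition == "first"


class TestCallSpecific:
    def r(self, tid, score):
        return SpecificityResult(tid, score, "c", score > 0.5)

    def test_partition_at_cutoff(self):
        results = [self.r("a", 1.0), self.r("b", 0.6), self.r("c", 0.3)]
        specific, non, frac_one = call_specific(results)
        assert [x.transcript_id for x in specific] == ["a", "b"]
        assert [x.transcript_id for x in non] == ["c"]
        assert frac_one == pytest.approx(1 / 3)

    def test_boundary_score_is_non_specific(self):
        specific, non, _ = call_specific([self.r("a", 0.5)])
        assert not specific and len(non) == 1

    def test_empty_input(self):
        assert call_specific([]) == ([], [], 0.0)


def test_score_matrix_reports_unscorable_rows():
    m = ExpressionMatrix.from_arrays(
        ["t1", "t2", "t3"], ["a", "b"],
        np.array([[1.0, 0.0], [0.0, 0.0], [2.0, 2.0]]))
    results, unscorable = score_matrix(m)
    assert [r.transcript_id for r in results] == ["t1", "t3"]
    assert unscorable == ["t2"]


def test_score_histogram_counts_sum():
    results = [SpecificityResult(f"t{i}", s, "c", False)
               for i, s in enumerate([0.0, 0.05, 0.5, 0.95, 1.0])]
    bins = score_histogram(results)
    assert sum(c for _, _, c in bins) == 5
    assert bins[-1][2] == 2  # 0.95 and 1.0 fall in the closed last bin
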