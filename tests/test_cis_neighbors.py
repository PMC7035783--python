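import itertools
import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from lincpipe.catalogue_compare import LocusSet
from lincpipe.cis_neighbors import correlate, find_neighbors, go_enrichment
from lincpipe.model import ExpressionMatrix, GenomicInterval


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestFindNeighbors:
    def test_gene_within_window(self):
        lincs = LocusSet("l", [("linc1", iv(100_000, 101_000))])
        spans = {"g1": iv(111_000, 112_000)}
        assert find_neighbors(lincs, spans) == [("linc1", "g1", 10_000)]

    def test_window_boundary_inclusive(self):
        lincs = LocusSet("l", [("linc1", iv(100_000, 101_000))])
        at_window = {"g1": iv(151_000, 152_000)}       # exactly 50,000 away
        beyond = {"g2": iv(151_001, 152_000)}          # 50,001 away
        assert find_neighbors(lincs, at_window, window=50_000) == [
            ("linc1", "g1", 50_000)]
        assert find_neighbors(lincs, beyond, window=50_000) == []

    def test_overlapping_spans_distance_zero(self):
        lincs = LocusSet("l", [("linc1", iv(100, 1000))])
        assert find_neighbors(lincs, {"g": iv(500, 2000)}) == [("linc1", "g", 0)]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        lincs = LocusSet("l", [
            (f"linc{i}", iv(int(s), int(s) + 1000, chrom=f"chr{i % 2}"))
            for i, s in enumerate(rng.integers(0, 500_000, size=60))
        ])
        spans = {
            f"g{i}": iv(int(s), int(s) + 5000, chrom=f"chr{i % 2}")
            for i, s in enumerate(rng.integers(0, 500_000, size=60))
        }
        window = 50_000
        expected = sorted(
            (linc, gid, l.distance_to(g))
            for linc, l in lincs.loci
            for gid, g in spans.items()
            if l.chrom == g.chrom and l.distance_to(g) <= window
        )
        assert find_neighbors(lincs, spans, window) == expected

    def test_window_symmetry(self):
        """gene within window of linc <=> linc within window of gene."""
        rng = np.random.default_rng(1)
        spans = {f"g{i}": iv(int(s), int(s) + 2000)
                 for i, s in enumerate(rng.integers(0, 200_000, size=30))}
        lincs = LocusSet("l", [(f"l{i}", iv(int(s), int(s) + 800))
                               for i, s in enumerate(rng.integers(0, 200_000, size=30))])
        forward = {(a, b) for a, b, _ in find_neighbors(lincs, spans)}
        flipped = find_neighbors(
            LocusSet("g", sorted(spans.items())),
            {name: v for name, v in lincs.loci})
        backward = {(b, a) for a, b, _ in flipped}
        assert forward == backward


class TestCorrelate:
    def matrices(self, linc_rows, gene_rows, conds=("a", "b", "c", "d")):
        linc = ExpressionMatrix.from_arrays(
            list(linc_rows), list(conds), np.array(list(linc_rows.values())))
        gene = ExpressionMatrix.from_arrays(
            list(gene_rows), list(conds), np.array(list(gene_rows.values())))
        return linc, gene

    def test_perfect_linear_relation(self):
        linc, gene = self.matrices({"l1": [1, 2, 3, 4]}, {"g1": [2, 4, 6, 8]})
        links, dropped = correlate([("l1", "g1", 0)], linc, gene)
        assert not dropped
        assert links[0].pcc == pytest.approx(1.0)
        assert links[0].strong

    def test_constant_profile_dropped(self):
        linc, gene = self.matrices({"l1": [1, 2, 3, 4]}, {"g1": [5, 5, 5, 5]})
        links, dropped = correlate([("l1", "g1", 0)], linc, gene)
        assert not links
        assert dropped == [("l1", "g1", "zero variance profile")]

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, size=6)
        y = rng.uniform(0, 10, size=6)
        conds = list("abcdef")
        base, gene = self.matrices({"l1": x}, {"g1": y}, conds)
        r0 = correlate([("l1", "g1", 0)], base, gene)[0][0].pcc
        scaled, gene2 = self.matrices({"l1": 3.5 * x + 2.0}, {"g1": y}, conds)
        r1 = correlate([("l1", "g1", 0)], scaled, gene2)[0][0].pcc
        assert r1 == pytest.approx(r0, abs=1e-12)
        assert abs(r0) <= 1.0

    def test_condition_mismatch_rejected(self):
        linc, _ = self.matrices({"l1": [1, 2, 3, 4]}, {"g1": [1, 2, 3, 4]})
        gene = ExpressionMatrix.from_arrays(
            ["g1"], ["w", "x", "y", "z"], np.array([[1.0, 2, 3, 4]]))
        with pytest.raises(ValueError):
            correlate([("l1", "g1", 0)], linc, gene)


class TestGoEnrichment:
    def test_term_in_every_background_gene_has_p_one(self):
        bg = [f"g{i}" for i in range(20)]
        go_map = {g: {"GO:1"} for g in bg}
        (res,) = go_enrichment(bg[:5], bg, go_map)
        assert res.p_value == pytest.approx(1.0)

    def test_tail_matches_direct_summation(self):
        # k=4, K=5, n=10, N=50
        bg = [f"g{i}" for i in range(50)]
        go_map = {g: {"GO:1"} for g in bg[:5]}
        fg = bg[:4] + bg[10:16]  # 10 genes, 4 carrying the term
        (res,) = go_enrichment(fg, bg, go_map)
        direct = sum(
            math.comb(5, k) * math.comb(45, 10 - k) / math.comb(50, 10)
            for k in range(4, 6)
        )
        assert (res.k, res.K, res.n, res.N) == (4, 5, 10, 50)
        assert res.p_value == pytest.approx(direct, rel=1e-12)

    def test_matches_exact_enumeration_small_universe(self):
        """For N=12 the hypergeometric tail equals exhaustive enumeration of
        all foreground draws."""
        bg = [f"g{i}" for i in range(12)]
        term_genes = set(bg[:5])
        go_map = {g: {"GO:1"} for g in term_genes}
        fg = bg[:3] + bg[5:8]  # n=6, k=3
        (res,) = go_enrichment(fg, bg, go_map)
        total = hits = 0
        for draw in itertools.combinations(bg, 6):
            total += 1
            if len(term_genes & set(draw)) >= 3:
                hits += 1
        assert res.p_value == pytest.approx(hits / total, rel=1e-12)

    def test_extreme_case_all_term_genes_drawn(self):
        # foreground = all genes with the term; K = n = k -> p = 1/C(N, K)
        bg = [f"g{i}" for i in range(10)]
        go_map = {g: {"GO:1"} for g in bg[:4]}
        (res,) = go_enrichment(bg[:4], bg, go_map)
        assert res.p_value == pytest.approx(1 / math.comb(10, 4), rel=1e-12)

    def test_p_monotone_decreasing_in_k(self):
        ps = [float(hypergeom.sf(k - 1, 50, 10, 15)) for k in range(0, 11)]
        assert ps == sorted(ps, reverse=True)

    def test_bh_preserves_raw_order_and_bounds(self):
        rng = np.random.default_rng(3)
        bg = [f"g{i}" for i in range(100)]
        go_map = {}
        for g in bg:
            terms = {f"GO:{t}" for t in rng.choice(10, size=3, replace=False)}
            go_map[g] = terms
        res = go_enrichment(bg[:20], bg, go_map)
        by_raw = sorted(res, key=lambda r: r.p_value)
        adj = [r.adjusted_p for r in by_raw]
        assert all(a <= b + 1e-12 for a, b in zip(adj, adj[1:]))
        assert all(0 < r.adjusted_p <= 1 for r in res)
        assert all(r.p_value <= r.adjusted_p + 1e-12 for r in res)

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValueError):
            go_enrichment([], ["g1"], {})

    def test_foreground_outside_background_rejected(self):
        with pytest.raises(ValueError):
            go_enrichment(["missing"], ["g1"], {})
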