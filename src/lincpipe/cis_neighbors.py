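"""Cis-regulatory candidate prediction.

Protein-coding genes lying within a window (default +/- 50 kb, inclusive) of
a tissue-specific lincRNA locus are its "neighbors". Each lincRNA-neighbor
pair is scored by the Pearson correlation of their expression profiles across
the shared conditions; strongly correlated neighbors (default |r| >= 0.9) are
tested for GO-term enrichment by the hypergeometric upper tail with
Benjamini-Hochberg correction within each GO category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .catalogue_compare import LocusSet
from .model import ExpressionMatrix, GenomicInterval

DEFAULT_WINDOW = 50_000
DEFAULT_PCC_THRESHOLD = 0.9
GO_CATEGORIES = ("BP", "MF", "CC")


@dataclass(frozen=True)
class NeighborLink:
    """A lincRNA paired with a protein-coding gene within the window."""

    lincrna_id: str
    gene_id: str
    distance: int
    pcc: float
    strong: bool


@dataclass(frozen=True)
class EnrichmentResult:
    go_term_id: str
    category: str
    k: int          # foreground genes carrying the term
    K: int          # background genes carrying the term
    n: int          # foreground size
    N: int          # background size
    p_value: float
    adjusted_p: float
    name: str = ""


def find_neighbors(
    lincs: LocusSet,
    gene_spans: Mapping[str, GenomicInterval],
    window: int = DEFAULT_WINDOW,
) -> list[tuple[str, str, int]]:
    """All (lincrna_id, gene_id, distance) pairs within the window.

    A gene is a neighbor iff its span overlaps the lincRNA span extended by
    ``window`` on both sides — equivalently, edge-to-edge distance <= window
    (inclusive; 0 for overlapping spans). Both strands are eligible. The
    relation is symmetric in the window sense.
    """
    trees: dict[str, IntervalTree] = {}
    for gid, span in gene_spans.items():
        trees.setdefault(span.chrom, IntervalTree()).addi(
            span.start, span.end, (gid, span)
        )
    pairs: list[tuple[str, str, int]] = []
    for linc_id, iv in lincs.loci:
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        # +1 because tree.overlap is exclusive of the query end; a gene at
        # exactly `window` bp must still be returned.
        for hit in tree.overlap(max(0, iv.start - window), iv.end + window + 1):
            gid, span = hit.data
            dist = iv.distance_to(span)
            if dist <= window:
                pairs.append((linc_id, gid, dist))
    pairs.sort()
    return pairs


def correlate(
    pairs: Sequence[tuple[str, str, int]],
    linc_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    threshold: float = DEFAULT_PCC_THRESHOLD,
) -> tuple[list[NeighborLink], list[tuple[str, str, str]]]:
    """Pearson correlation for each neighbor pair across shared conditions.

    The two matrices must declare the same ordered condition set. Pairs with
    zero variance on either side have undefined correlation and are returned
    in the dropped list with a reason instead of a link.
    """
    if linc_expr.condition_names != gene_expr.condition_names:
        raise ValueError("expression matrices disagree on conditions")
    links: list[NeighborLink] = []
    dropped: list[tuple[str, str, str]] = []
    for linc_id, gene_id, dist in pairs:
        if linc_id not in linc_expr:
            dropped.append((linc_id, gene_id, "lincRNA missing from expression"))
            continue
        if gene_id not in gene_expr:
            dropped.append((linc_id, gene_id, "gene missing from expression"))
            continue
        x = linc_expr.row(linc_id)
        y = gene_expr.row(gene_id)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            dropped.append((linc_id, gene_id, "zero variance profile"))
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        links.append(NeighborLink(linc_id, gene_id, dist, r, abs(r) >= threshold))
    return links, dropped


def go_enrichment(
    foreground: Iterable[str],
    background: Iterable[str],
    go_map: Mapping[str, set[str]],
    term_meta: Optional[Mapping[str, tuple[str, str]]] = None,
) -> list[EnrichmentResult]:
    """Hypergeometric GO-term over-representation of ``foreground`` genes.

    For each term annotated to >= 1 background gene: p = P(X >= k) with X ~
    Hypergeom(N, K, n). BH adjustment is applied across the tested terms
    within each GO category (terms without metadata fall into one pooled
    category). Results are sorted by adjusted then raw p-value.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg:
        raise ValueError("empty foreground gene set")
    if not fg <= bg:
        raise ValueError("foreground must be a subset of the background")
    term_genes: dict[str, set[str]] = {}
    for gene in bg:
        for term in go_map.get(gene, ()):
            term_genes.setdefault(term, set()).add(gene)
    N, n = len(bg), len(fg)
    by_category: dict[str, list[EnrichmentResult]] = {}
    for term, genes in term_genes.items():
        K = len(genes)
        k = len(genes & fg)
        p = float(hypergeom.sf(k - 1, N, K, n))
        category, name = ("", "")
        if term_meta is not None and term in term_meta:
            category, name = term_meta[term]
        by_category.setdefault(category, []).append(
            EnrichmentResult(term, category, k, K, n, N, min(p, 1.0), 1.0, name)
        )
    results: list[EnrichmentResult] = []
    for category, items in by_category.items():
        raw = [r.p_value for r in items]
        _, adjusted, _, _ = multipletests(raw, method="fdr_bh")
        for r, adj in zip(items, adjusted):
            results.append(
                EnrichmentResult(r.go_term_id, r.category, r.k, r.K, r.n, r.N,
                                 r.p_value, float(adj), r.name)
            )
    results.sort(key=lambda r: (r.adjusted_p, r.p_value, r.go_term_id))
    return results
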