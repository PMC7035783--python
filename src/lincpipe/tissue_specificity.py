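"""Entropy-based tissue-specificity scoring.

The specificity of an expression pattern is 1 minus the square root of the
Jensen-Shannon divergence (Shannon entropy in bits) between the normalized
pattern and the extremal single-condition pattern, maximized over conditions.
A transcript expressed in exactly one condition scores exactly 1; spreading
expression over more conditions lowers the score. Transcripts scoring above
the cutoff (default 0.5, strict inequality) are called tissue-specific.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import ExpressionMatrix

DEFAULT_JS_CUTOFF = 0.5


class ScoreError(ValueError):
    """Raised for inputs that violate the scorer's preconditions."""


@dataclass(frozen=True)
class SpecificityResult:
    transcript_id: str
    js_score: float
    argmax_condition: str
    is_specific: bool


def _entropy_bits(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def js_divergence(p: Sequence[float], q: Sequence[float]) -> float:
    """Jensen-Shannon divergence H((p+q)/2) - (H(p)+H(q))/2 in bits.

    Both arguments must be probability vectors of equal length n >= 2
    (entries >= 0, summing to 1 within 1e-9). The result lies in [0, 1],
    reaching 1 exactly for distributions with disjoint support.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1 or p.size < 2:
        raise ScoreError("p and q must be equal-length vectors of size >= 2")
    for vec in (p, q):
        if (vec < 0).any():
            raise ScoreError("probability vectors must be non-negative")
        if abs(vec.sum() - 1.0) > 1e-9:
            raise ScoreError("probability vectors must sum to 1 (tolerance 1e-9)")
    m = (p + q) / 2.0
    return _entropy_bits(m) - (_entropy_bits(p) + _entropy_bits(q)) / 2.0


def specificity_score(
    expression: Sequence[float],
    condition_names: Optional[Sequence[str]] = None,
    transcript_id: str = "",
    cutoff: float = DEFAULT_JS_CUTOFF,
) -> SpecificityResult:
    """Maximal JS specificity score of one expression vector.

    The vector is normalized to a distribution; the score is evaluated
    against every single-condition extremal pattern and the maximum taken,
    with ties broken by the first condition in declared order. Invariant to
    positive rescaling of the input. All-zero vectors are not scorable.
    """
    e = np.asarray(expression, dtype=float)
    if e.ndim != 1 or e.size < 2:
        raise ScoreError("expression vector must have >= 2 conditions")
    if (e < 0).any():
        raise ScoreError("expression values must be non-negative")
    if not (e > 0).any():
        raise ScoreError(f"all-zero expression vector ({transcript_id!r}) is not scorable")
    if condition_names is None:
        condition_names = [f"condition_{i}" for i in range(e.size)]
    p = e / e.sum()
    best_score = -np.inf
    best_idx = 0
    for t in range(e.size):
        unit = np.zeros(e.size)
        unit[t] = 1.0
        score = 1.0 - np.sqrt(js_divergence(p, unit))
        if score > best_score:
            best_score, best_idx = score, t
    return SpecificityResult(
        transcript_id=transcript_id,
        js_score=float(best_score),
        argmax_condition=str(condition_names[best_idx]),
        is_specific=bool(best_score > cutoff),
    )


def score_matrix(
    matrix: ExpressionMatrix, cutoff: float = DEFAULT_JS_CUTOFF
) -> tuple[list[SpecificityResult], list[str]]:
    """Score every row of an expression matrix.

    Returns (results, unscorable_ids); all-zero rows are excluded from the
    results and reported by id rather than silently dropped.
    """
    results: list[SpecificityResult] = []
    unscorable: list[str] = []
    conditions = matrix.condition_names
    for tid in matrix.transcript_ids:
        row = matrix.row(tid)
        if not (row > 0).any():
            unscorable.append(tid)
            continue
        results.append(specificity_score(row, conditions, tid, cutoff))
    return results, unscorable


def call_specific(
    results: Sequence[SpecificityResult], cutoff: float = DEFAULT_JS_CUTOFF
) -> tuple[list[SpecificityResult], list[SpecificityResult], float]:
    """Partition results at the cutoff (strictly greater = specific).

    Also reports the fraction of transcripts scoring exactly 1 (expressed in
    a single condition). Returns (specific, non_specific, fraction_at_one).
    """
    specific = [r for r in results if r.js_score > cutoff]
    non_specific = [r for r in results if r.js_score <= cutoff]
    frac_one = (
        sum(1 for r in results if r.js_score == 1.0) / len(results)
        if results else 0.0
    )
    return specific, non_specific, frac_one


def score_histogram(
    results: Sequence[SpecificityResult], n_bins: int = 10
) -> list[tuple[float, float, int]]:
    """Counts of scores in equal-width bins over [0, 1] (last bin closed)."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram([r.js_score for r in results], bins=edges)
    return [
        (float(edges[i]), float(edges[i + 1]), int(counts[i])) for i in range(n_bins)
    ]
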