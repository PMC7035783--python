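"""Alignment-free coding-potential assessment and the noncoding filter cascade.

The scorer follows the CPAT recipe: four sequence features — maximal ORF
length, ORF coverage, the Fickett TESTCODE statistic, and hexamer usage bias
— combined by a logistic model trained on labelled coding/noncoding sequences,
with the decision cutoff chosen on held-out data by maximizing
sensitivity + specificity (two-graph ROC). Around the trained scorer sit the
three decision rules of the identification pipeline: a conservation-score rule
(negative score = noncoding evidence), a protein-domain rule (any recorded
hit excludes), and a maximal-ORF length rule (> ``max_orf_aa`` amino acids
excludes). A transcript is called noncoding only if every applicable rule
passes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODON = "ATG"

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

FEATURE_NAMES = ("orf_nt_length", "orf_coverage", "fickett_score", "hexamer_score")

# ---------------------------------------------------------------------------
# Fickett TESTCODE statistic (published lookup tables, as adopted by CPAT).
# The "position" parameter of a base is max/(min+1) over its counts at the
# three codon positions; the "content" parameter is its overall frequency.
# Each parameter is converted to a coding probability via the tables below
# and the eight probabilities are combined by the published weights.
# ---------------------------------------------------------------------------

_POSITION_THRESHOLDS = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0)
_CONTENT_THRESHOLDS = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0)

_POSITION_PROB = {
    "A": (0.51, 0.55, 0.57, 0.52, 0.48, 0.58, 0.57, 0.54, 0.50, 0.36),
    "C": (0.29, 0.44, 0.55, 0.49, 0.39, 0.24, 0.26, 0.24, 0.30, 0.23),
    "G": (0.62, 0.67, 0.74, 0.65, 0.61, 0.62, 0.46, 0.39, 0.17, 0.20),
    "T": (0.51, 0.60, 0.69, 0.64, 0.53, 0.48, 0.52, 0.34, 0.20, 0.09),
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}

_CONTENT_PROB = {
    "A": (0.40, 0.55, 0.58, 0.58, 0.52, 0.48, 0.45, 0.45, 0.38, 0.19),
    "C": (0.50, 0.63, 0.59, 0.50, 0.41, 0.31, 0.28, 0.24, 0.30, 0.33),
    "G": (0.21, 0.40, 0.58, 0.61, 0.66, 0.81, 0.70, 0.62, 0.42, 0.25),
    "T": (0.30, 0.49, 0.56, 0.53, 0.48, 0.48, 0.34, 0.20, 0.12, 0.22),
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}


@dataclass(frozen=True)
class Orf:
    """A maximal open reading frame in a transcript sequence.

    ``end`` includes the stop codon when one terminates the ORF; ``aa_length``
    excludes the stop. ORFs without an in-frame stop run to the last complete
    codon of the frame.
    """

    frame: int
    start: int
    end: int
    stop_terminated: bool

    @property
    def nt_length(self) -> int:
        return self.end - self.start

    @property
    def aa_length(self) -> int:
        n_codons = self.nt_length // 3
        return n_codons - 1 if self.stop_terminated else n_codons


@dataclass(frozen=True)
class CodingFeatures:
    orf_nt_length: int
    orf_coverage: float
    fickett_score: float
    hexamer_score: float

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.orf_nt_length, self.orf_coverage,
             self.fickett_score, self.hexamer_score], dtype=float
        )


@dataclass(frozen=True)
class CodingPotentialResult:
    """Per-transcript scores and pass/fail flags of the four noncoding filters."""

    transcript_id: str
    features: CodingFeatures
    logistic_probability: float
    conservation_score: Optional[float]
    domain_hit: Optional[bool]
    passes_cpat: bool
    passes_conservation: bool
    passes_domain: bool
    passes_maxorf: bool

    @property
    def is_noncoding_call(self) -> bool:
        return (
            self.passes_cpat
            and self.passes_conservation
            and self.passes_domain
            and self.passes_maxorf
        )


def find_max_orf(seq: str) -> Orf:
    """Longest ATG-initiated ORF over the three forward frames.

    An ORF ends at the first in-frame stop (stop codon included in the span);
    with no stop it extends to the last complete codon. Codons containing N
    never match ATG or a stop. Ties on length resolve to the smallest start,
    then the lowest frame. Sequences shorter than 3 yield a zero-length ORF.
    """
    seq = seq.upper()
    best: Optional[Orf] = None
    for frame in range(3):
        start: Optional[int] = None
        i = frame
        last_complete = frame + ((len(seq) - frame) // 3) * 3
        while i + 3 <= len(seq):
            codon = seq[i:i + 3]
            if start is None:
                if codon == START_CODON:
                    start = i
            elif codon in STOP_CODONS:
                cand = Orf(frame, start, i + 3, True)
                best = _better_orf(best, cand)
                start = None
            i += 3
        if start is not None:
            cand = Orf(frame, start, last_complete, False)
            best = _better_orf(best, cand)
    if best is None:
        return Orf(0, 0, 0, False)
    return best


def _better_orf(best: Optional[Orf], cand: Orf) -> Orf:
    if best is None:
        return cand
    key_best = (-best.nt_length, best.start, best.frame)
    key_cand = (-cand.nt_length, cand.start, cand.frame)
    return cand if key_cand < key_best else best


def _lookup(value: float, thresholds: Sequence[float],
            probs: Sequence[float]) -> float:
    for t, p in zip(thresholds, probs):
        if value >= t:
            return p
    return probs[-1]


def fickett(seq: str) -> float:
    """Fickett TESTCODE statistic of a nucleotide sequence.

    Ambiguous bases (N) are excluded from the counts. Deterministic; depends
    only on base composition and codon-position asymmetry, so duplicating a
    sequence in register (seq+seq+seq) leaves it unchanged.
    """
    seq = seq.upper()
    pos_counts = {b: [0, 0, 0] for b in "ACGT"}
    totals = {b: 0 for b in "ACGT"}
    n_counted = 0
    for i, base in enumerate(seq):
        if base in _BASE_INDEX:
            pos_counts[base][i % 3] += 1
            totals[base] += 1
            n_counted += 1
    score = 0.0
    for base in "ACGT":
        counts = pos_counts[base]
        position_param = max(counts) / (min(counts) + 1)
        content_param = totals[base] / n_counted if n_counted else 0.0
        score += _lookup(position_param, _POSITION_THRESHOLDS,
                         _POSITION_PROB[base]) * _POSITION_WEIGHT[base]
        score += _lookup(content_param, _CONTENT_THRESHOLDS,
                         _CONTENT_PROB[base]) * _CONTENT_WEIGHT[base]
    return score


def _hexamer_index(hexamer: str) -> Optional[int]:
    idx = 0
    for base in hexamer:
        code = _BASE_INDEX.get(base)
        if code is None:
            return None
        idx = idx * 4 + code
    return idx


@dataclass
class HexamerTable:
    """In-frame hexamer frequencies of coding vs noncoding training sequences.

    Both 4096-entry frequency vectors are add-one pseudocounted and normalized
    to sum to 1, so every log-ratio is finite.
    """

    coding_freq: np.ndarray
    noncoding_freq: np.ndarray

    def __post_init__(self) -> None:
        for freq in (self.coding_freq, self.noncoding_freq):
            if freq.shape != (4096,):
                raise ValueError("hexamer frequency vector must have 4096 entries")
            if (freq <= 0).any() or not math.isclose(freq.sum(), 1.0, abs_tol=1e-9):
                raise ValueError("hexamer frequencies must be positive and normalized")

    @property
    def log_ratio(self) -> np.ndarray:
        return np.log(self.coding_freq) - np.log(self.noncoding_freq)

    def to_dict(self) -> dict:
        return {
            "coding_freq": self.coding_freq.tolist(),
            "noncoding_freq": self.noncoding_freq.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HexamerTable":
        return cls(np.asarray(d["coding_freq"]), np.asarray(d["noncoding_freq"]))


def _count_hexamers(seqs: Sequence[str], step: int) -> np.ndarray:
    counts = np.zeros(4096)
    for seq in seqs:
        seq = seq.upper()
        for i in range(0, len(seq) - 5, step):
            idx = _hexamer_index(seq[i:i + 6])
            if idx is not None:
                counts[idx] += 1
    return counts


def train_hexamer_table(
    coding: Sequence[str], noncoding: Sequence[str], pseudocount: float = 1.0
) -> HexamerTable:
    """Tally in-frame (step 3) hexamers of CDS vs sliding (step 1) hexamers
    of noncoding sequences, with add-one pseudocounts.

    Coding sequences are read in frame from position 0.
    """
    if not coding or not noncoding:
        raise ValueError("both training sets must be non-empty")
    c = _count_hexamers(coding, step=3) + pseudocount
    n = _count_hexamers(noncoding, step=1) + pseudocount
    return HexamerTable(c / c.sum(), n / n.sum())


def hexamer_score(seq_orf: str, table: HexamerTable) -> float:
    """Mean log(F_coding/F_noncoding) over in-frame hexamers of an ORF sequence.

    Hexamers containing N are skipped; with no scorable hexamer the score is 0.
    Antisymmetric under swapping the two training sets.
    """
    seq_orf = seq_orf.upper()
    log_ratio = table.log_ratio
    total = 0.0
    count = 0
    for i in range(0, len(seq_orf) - 5, 3):
        idx = _hexamer_index(seq_orf[i:i + 6])
        if idx is not None:
            total += log_ratio[idx]
            count += 1
    return total / count if count else 0.0


def extract_features(seq: str, table: HexamerTable) -> CodingFeatures:
    orf = find_max_orf(seq)
    coverage = orf.nt_length / len(seq) if seq else 0.0
    return CodingFeatures(
        orf_nt_length=orf.nt_length,
        orf_coverage=coverage,
        fickett_score=fickett(seq),
        hexamer_score=hexamer_score(seq[orf.start:orf.end], table),
    )


@dataclass
class CodingModel:
    """Logistic model over the four coding features, with a trained cutoff."""

    coefficients: dict[str, float]
    intercept: float
    cutoff: float
    hexamer_table: HexamerTable

    def __post_init__(self) -> None:
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError("cutoff must lie strictly between 0 and 1")

    def probability(self, features: CodingFeatures) -> float:
        logit = self.intercept + sum(
            self.coefficients[name] * value
            for name, value in zip(FEATURE_NAMES, features.as_vector())
        )
        return 1.0 / (1.0 + math.exp(-logit))

    def score_sequence(self, seq: str) -> tuple[CodingFeatures, float]:
        features = extract_features(seq, self.hexamer_table)
        return features, self.probability(features)

    def save(self, path: str | Path) -> None:
        payload = {
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "cutoff": self.cutoff,
            "hexamer_table": self.hexamer_table.to_dict(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "CodingModel":
        d = json.loads(Path(path).read_text())
        return cls(
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            intercept=float(d["intercept"]),
            cutoff=float(d["cutoff"]),
            hexamer_table=HexamerTable.from_dict(d["hexamer_table"]),
        )


def fit_coding_model(
    coding_seqs: Sequence[str],
    noncoding_seqs: Sequence[str],
    held_out_fraction: float = 0.25,
    seed: int = 0,
) -> CodingModel:
    """Train the hexamer table and logistic model; pick the cutoff on held-out data.

    The cutoff is the probability threshold maximizing sensitivity +
    specificity on the held-out split (the two-graph ROC optimum), evaluated
    at midpoints between adjacent held-out probabilities so it always lies
    strictly inside (0, 1).
    """
    if len(coding_seqs) < 50 or len(noncoding_seqs) < 50:
        raise ValueError("need >= 50 sequences per class")
    seqs = list(coding_seqs) + list(noncoding_seqs)
    labels = np.array([1] * len(coding_seqs) + [0] * len(noncoding_seqs))
    idx_train, idx_test = train_test_split(
        np.arange(len(seqs)), test_size=held_out_fraction,
        random_state=seed, stratify=labels,
    )
    table = train_hexamer_table(
        [seqs[i] for i in idx_train if labels[i] == 1],
        [seqs[i] for i in idx_train if labels[i] == 0],
    )
    X = np.array([extract_features(s, table).as_vector() for s in seqs])
    clf = LogisticRegression(max_iter=5000)
    clf.fit(X[idx_train], labels[idx_train])

    probs_test = clf.predict_proba(X[idx_test])[:, 1]
    y_test = labels[idx_test]
    candidates = np.unique(probs_test)
    midpoints = (candidates[:-1] + candidates[1:]) / 2.0
    cutoffs = np.concatenate([[0.5], midpoints]) if midpoints.size else np.array([0.5])
    best_cutoff, best_j = 0.5, -np.inf
    n_pos = max(1, int((y_test == 1).sum()))
    n_neg = max(1, int((y_test == 0).sum()))
    for cut in cutoffs:
        if not 0.0 < cut < 1.0:
            continue
        pred = probs_test >= cut
        sens = (pred & (y_test == 1)).sum() / n_pos
        spec = (~pred & (y_test == 0)).sum() / n_neg
        if sens + spec > best_j:
            best_j, best_cutoff = sens + spec, float(cut)
    return CodingModel(
        coefficients=dict(zip(FEATURE_NAMES, clf.coef_[0].tolist())),
        intercept=float(clf.intercept_[0]),
        cutoff=best_cutoff,
        hexamer_table=table,
    )


def apply_noncoding_filters(
    transcript_id: str,
    seq: str,
    model: CodingModel,
    conservation_scores: Optional[dict[str, float]] = None,
    domain_hits: Optional[set[str]] = None,
    max_orf_aa: int = 100,
) -> CodingPotentialResult:
    """Evaluate the four noncoding decision rules for one transcript.

    passes_cpat          probability < model cutoff
    passes_conservation  conservation score < 0 when one is provided, else pass
    passes_domain        no recorded domain hit when a table is provided, else pass
    passes_maxorf        maximal ORF <= ``max_orf_aa`` amino acids

    A score of exactly 0 fails the conservation rule (only negative scores
    are retained as noncoding evidence).
    """
    features, prob = model.score_sequence(seq)
    score = None
    if conservation_scores is not None:
        score = conservation_scores.get(transcript_id)
    hit = None
    if domain_hits is not None:
        hit = transcript_id in domain_hits
    orf = find_max_orf(seq)
    return CodingPotentialResult(
        transcript_id=transcript_id,
        features=features,
        logistic_probability=prob,
        conservation_score=score,
        domain_hit=hit,
        passes_cpat=prob < model.cutoff,
        passes_conservation=(score is None) or (score < 0),
        passes_domain=(hit is None) or (not hit),
        passes_maxorf=orf.aa_length <= max_orf_aa,
    )


def translate_three_frames(seq: str) -> tuple[str, str, str]:
    """Standard-code translation of the three forward frames.

    Stops are rendered as "*"; codons containing N translate to "X" (unless
    the ambiguity resolves to one amino acid). Trailing partial codons are
    dropped. Used to export peptides for external domain scanning.
    """
    seq = seq.upper()
    frames = []
    for frame in range(3):
        sub = seq[frame:]
        sub = sub[: (len(sub) // 3) * 3]
        frames.append(str(Seq(sub).translate()))
    return tuple(frames)  # type: ignore[return-value]
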