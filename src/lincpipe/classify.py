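"""Class-code assignment of assembled transcripts against a reference annotation.

Each assembled transcript ("transfrag") receives one single-character code
describing its relation to the reference transcripts, following the
Cuffcompare vocabulary:

=  complete match of intron chain                 (same strand)
c  contained: exons within reference exons, introns a subset, fewer exons
j  shares >= 1 splice junction, intron chains differ (potentially novel isoform)
e  single-exon transfrag overlapping a reference exon and >= 10 bp of
   reference intron
i  entirely within a reference intron
o  other exonic overlap with a reference
p  possible polymerase run-on fragment: no exonic overlap, within the run-on
   distance downstream of a same-strand reference 3' end
x  exonic overlap with a reference on the opposite strand
s  contained in a reference intron on the opposite strand
u  unknown, intergenic transcript (none of the above)

When several references overlap a transfrag, the most specific code wins in
the fixed precedence order = > c > j > e > o > i > x > s > p > u; ties across
references are broken by larger exonic overlap in bp, then lexicographically
smaller reference id, so results are deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

from intervaltree import IntervalTree

from .model import GenomicInterval, TranscriptModel

CLASS_CODES = ("=", "c", "j", "e", "i", "o", "p", "u", "x", "s")

#: Specificity order used to resolve multiple overlapping references.
PRECEDENCE = {code: rank for rank, code in enumerate(
    ("=", "c", "j", "e", "o", "i", "x", "s", "p", "u"))}

#: Minimum intrusion into a reference intron for the "e" code.
E_MIN_INTRON_BP = 10

#: Default downstream distance for the run-on ("p") code.
DEFAULT_RUN_ON_DISTANCE = 2000


@dataclass(frozen=True)
class ClassCodedTranscript:
    """A transcript plus its assigned class code and best-matching reference."""

    transcript: TranscriptModel
    code: str
    best_reference: str = ""

    def __post_init__(self) -> None:
        if self.code not in CLASS_CODES:
            raise ValueError(f"unknown class code {self.code!r}")
        if self.code == "u" and self.best_reference:
            raise ValueError('"u" transcripts cannot carry a reference match')


class ReferenceIndex:
    """Chromosome-keyed interval index over reference transcript spans.

    Overlap queries return exactly the references a linear scan would.
    """

    def __init__(self, refs: Iterable[TranscriptModel]):
        self._trees: dict[str, IntervalTree] = {}
        self.references = list(refs)
        for ref in self.references:
            span = ref.interval
            self._trees.setdefault(span.chrom, IntervalTree()).addi(
                span.start, span.end, ref
            )

    def query(self, chrom: str, start: int, end: int) -> list[TranscriptModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [hit.data for hit in tree.overlap(start, end)]
        return sorted(hits, key=lambda r: (r.interval.start, r.transcript_id))


def build_interval_index(refs: Iterable[TranscriptModel]) -> ReferenceIndex:
    return ReferenceIndex(refs)


def _exonic_overlap_bp(t: TranscriptModel, ref: TranscriptModel) -> int:
    return sum(te.overlap_bp(re_) for te in t.exons for re_ in ref.exons)


def _within_an_intron(span: GenomicInterval, ref: TranscriptModel) -> bool:
    return any(
        istart <= span.start and span.end <= iend for istart, iend in ref.introns
    )


def _code_vs_reference(
    t: TranscriptModel, ref: TranscriptModel, run_on_distance: int
) -> Optional[str]:
    """Code describing t's relation to one reference, or None for no relation.

    Strand-unknown transfrags are compared against both strands but are never
    eligible for "=" or "j" (intron-chain codes need orientation), nor for the
    opposite-strand codes "x"/"s".
    """
    if t.chrom != ref.chrom:
        return None
    span = t.interval
    opposite = t.strand != "." and ref.strand != "." and t.strand != ref.strand
    ov = _exonic_overlap_bp(t, ref)

    if opposite:
        if ov > 0:
            return "x"
        if _within_an_intron(span, ref):
            return "s"
        return None

    stranded_match = t.strand != "." and t.strand == ref.strand
    if (
        stranded_match
        and t.is_multi_exon
        and ref.is_multi_exon
        and t.introns == ref.introns
    ):
        return "="
    ref_introns = set(ref.introns)
    if (
        len(t.exons) < len(ref.exons)
        and all(
            any(re_.start <= te.start and te.end <= re_.end for re_ in ref.exons)
            for te in t.exons
        )
        and all(intron in ref_introns for intron in t.introns)
    ):
        return "c"
    if stranded_match and t.is_multi_exon and any(
        intron in ref_introns for intron in t.introns
    ):
        return "j"
    if not t.is_multi_exon and ov > 0:
        exon = t.exons[0]
        intron_bp = sum(
            exon.overlap_bp(GenomicInterval(ref.chrom, istart, iend, ref.strand))
            for istart, iend in ref.introns
        )
        if intron_bp >= E_MIN_INTRON_BP:
            return "e"
    if ov > 0:
        return "o"
    if _within_an_intron(span, ref):
        return "i"
    # run-on fragment: downstream of the reference 3' end on the ref strand
    if ref.strand == "+" and span.start >= ref.interval.end:
        if span.start - ref.interval.end <= run_on_distance:
            return "p"
    elif ref.strand == "-" and span.end <= ref.interval.start:
        if ref.interval.start - span.end <= run_on_distance:
            return "p"
    return None


def assign_class_code(
    t: TranscriptModel,
    index: ReferenceIndex,
    run_on_distance: int = DEFAULT_RUN_ON_DISTANCE,
) -> ClassCodedTranscript:
    """Assign the most specific class code over all references near ``t``."""
    span = t.interval
    window_start = max(0, span.start - run_on_distance)
    candidates = index.query(t.chrom, window_start, span.end + run_on_distance)
    best: Optional[tuple[int, int, str, str]] = None
    for ref in candidates:
        code = _code_vs_reference(t, ref, run_on_distance)
        if code is None:
            continue
        key = (
            PRECEDENCE[code],
            -_exonic_overlap_bp(t, ref),
            ref.transcript_id,
            code,
        )
        if best is None or key < best:
            best = key
    if best is None:
        return ClassCodedTranscript(t, "u", "")
    return ClassCodedTranscript(t, best[3], best[2])


def classify_all(
    transcripts: Iterable[TranscriptModel],
    refs: Iterable[TranscriptModel],
    run_on_distance: int = DEFAULT_RUN_ON_DISTANCE,
) -> list[ClassCodedTranscript]:
    index = build_interval_index(refs)
    return [assign_class_code(t, index, run_on_distance) for t in transcripts]


def select_candidates(coded: Iterable[ClassCodedTranscript]) -> list[TranscriptModel]:
    """Multi-exon unknown-intergenic transcripts: the lincRNA candidate pool."""
    return [
        c.transcript for c in coded if c.code == "u" and c.transcript.is_multi_exon
    ]


def summarize_classes(coded: Iterable[ClassCodedTranscript]) -> dict[str, int]:
    """Per-code transcript counts over all codes (zeros included)."""
    tally = Counter(c.code for c in coded)
    return {code: tally.get(code, 0) for code in CLASS_CODES}
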