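"""Core genomic data model.

All coordinates are 0-based half-open throughout the package; format readers
and writers convert at the boundary (GTF is 1-based inclusive, BED is native
0-based half-open).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Strand symbols. "." marks an unknown / unreported strand.
STRANDS = ("+", "-", ".")

#: Biotypes a transcript may carry.
BIOTYPES = ("protein_coding", "known_noncoding", "small_rna", "assembled_unknown")


class ValidationError(ValueError):
    """Raised when a record violates a data-model invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded interval on a chromosome, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strand-blind overlap test; intervals on different chroms never overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance_to(self, other: "GenomicInterval") -> int:
        """Edge-to-edge distance in bp; 0 when the intervals overlap or abut."""
        if self.chrom != other.chrom:
            raise ValidationError("distance undefined across chromosomes")
        return max(0, max(self.start, other.start) - min(self.end, other.end))


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, exon-structured transcript — the unit flowing through every filter.

    Invariants enforced at construction: exons share the transcript's chrom and
    strand, are sorted by start, do not overlap, and successive exons are
    separated by introns of length >= 1.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    biotype: str = "assembled_unknown"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript needs >= 1 exon")
        if self.biotype not in BIOTYPES:
            raise ValidationError(f"{self.transcript_id}: bad biotype {self.biotype!r}")
        chrom = self.exons[0].chrom
        strand = self.exons[0].strand
        prev_end = None
        for exon in self.exons:
            if exon.chrom != chrom or exon.strand != strand:
                raise ValidationError(
                    f"{self.transcript_id}: exons disagree on chrom/strand"
                )
            if prev_end is not None and exon.start <= prev_end:
                if exon.start < prev_end:
                    raise ValidationError(
                        f"{self.transcript_id}: overlapping exons"
                    )
                raise ValidationError(
                    f"{self.transcript_id}: zero-length intron between exons"
                )
            prev_end = exon.end
        object.__setattr__(self, "exons", tuple(self.exons))

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def interval(self) -> GenomicInterval:
        """Genomic span: first exon start to last exon end."""
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Intron chain as (start, end) coordinate pairs (splice junctions)."""
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons[:-1], self.exons[1:])
        )

    @property
    def is_multi_exon(self) -> bool:
        return len(self.exons) > 1

    @property
    def spliced_length(self) -> int:
        """Sum of exon lengths (the mature transcript length)."""
        return sum(len(e) for e in self.exons)


@dataclass
class ExpressionMatrix:
    """Transcripts x conditions FPKM values.

    Thin wrapper over a pandas DataFrame (rows = transcripts, columns =
    conditions) that enforces non-negativity and consistent labelling.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if values.size and (np.isnan(values).any() or (values < 0).any()):
            raise ValidationError("expression values must be non-negative and present")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate transcript ids in expression matrix")

    @classmethod
    def from_arrays(
        cls,
        transcript_ids: Sequence[str],
        condition_names: Sequence[str],
        values: np.ndarray,
    ) -> "ExpressionMatrix":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(transcript_ids), len(condition_names)):
            raise ValidationError("expression matrix shape/label mismatch")
        return cls(pd.DataFrame(values, index=list(transcript_ids),
                                columns=list(condition_names)))

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def condition_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def row(self, transcript_id: str) -> np.ndarray:
        return self.data.loc[transcript_id].to_numpy(dtype=float)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.data.index


def gene_spans(transcripts: Iterable[TranscriptModel]) -> dict[str, GenomicInterval]:
    """Union span per gene_id (min start to max end across its transcripts)."""
    spans: dict[str, GenomicInterval] = {}
    for t in transcripts:
        iv = t.interval
        prev = spans.get(t.gene_id)
        if prev is None:
            spans[t.gene_id] = iv
        else:
            if prev.chrom != iv.chrom:
                raise ValidationError(f"gene {t.gene_id} spans multiple chromosomes")
            strand = prev.strand if prev.strand == iv.strand else "."
            spans[t.gene_id] = GenomicInterval(
                prev.chrom, min(prev.start, iv.start), max(prev.end, iv.end), strand
            )
    return spans
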