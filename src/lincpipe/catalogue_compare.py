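"""Locus-overlap comparison between lincRNA catalogues.

Catalogues from different studies are compared at the genomic-locus level
(transcript span intervals), strand-blind with a 1 bp minimum overlap by
default, since external catalogues vary in strand reliability. Produces
shared/unique counts and Venn-style region counts against multiple sets.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from . import io_formats
from .model import GenomicInterval, TranscriptModel, ValidationError


@dataclass
class LocusSet:
    """A named catalogue of named genomic loci."""

    name: str
    loci: list[tuple[str, GenomicInterval]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.loci]
        if len(names) != len(set(names)):
            raise ValidationError(f"locus set {self.name!r} has duplicate locus names")

    def __len__(self) -> int:
        return len(self.loci)

    @classmethod
    def from_bed(cls, path: str | Path, name: str | None = None) -> "LocusSet":
        return cls(name or Path(path).stem, io_formats.read_bed(path))

    @classmethod
    def from_transcripts(
        cls, name: str, transcripts: Iterable[TranscriptModel]
    ) -> "LocusSet":
        return cls(name, [(t.transcript_id, t.interval) for t in transcripts])

    def to_bed(self, path: str | Path) -> None:
        io_formats.write_bed(self.loci, path)


def _build_tree(loci: Sequence[tuple[str, GenomicInterval]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for _, iv in loci:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def _is_shared(
    iv: GenomicInterval, trees: dict[str, IntervalTree], min_overlap_bp: int
) -> bool:
    tree = trees.get(iv.chrom)
    if tree is None:
        return False
    return any(
        min(iv.end, hit.end) - max(iv.start, hit.begin) >= min_overlap_bp
        for hit in tree.overlap(iv.start, iv.end)
    )


def overlap_catalogues(
    a: LocusSet, b: LocusSet, min_overlap_bp: int = 1
) -> tuple[list[str], dict[str, int]]:
    """Loci of ``a`` overlapping any locus of ``b`` by >= ``min_overlap_bp``.

    Overlap is strand-blind. Returns (names of shared loci of a, counts with
    keys "shared" and "unique"); shared + unique = |a|.
    """
    trees = _build_tree(b.loci)
    shared = [
        name for name, iv in a.loci if _is_shared(iv, trees, min_overlap_bp)
    ]
    return shared, {"shared": len(shared), "unique": len(a) - len(shared)}


def multi_set_membership(
    primary: LocusSet,
    others: Sequence[LocusSet],
    min_overlap_bp: int = 1,
) -> tuple[dict[str, tuple[bool, ...]], dict[tuple[bool, ...], int]]:
    """Per-locus membership of ``primary`` in each other catalogue.

    Returns (membership, region_counts): membership maps each primary locus
    name to a flag per other set (in the given order); region_counts tallies
    every membership combination — the Venn regions — and partitions
    ``primary`` (counts sum to |primary|).
    """
    if not others:
        raise ValueError("need at least one catalogue to compare against")
    trees = [_build_tree(o.loci) for o in others]
    membership: dict[str, tuple[bool, ...]] = {}
    for name, iv in primary.loci:
        membership[name] = tuple(
            _is_shared(iv, t, min_overlap_bp) for t in trees
        )
    region_counts = dict(Counter(membership.values()))
    return membership, region_counts
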