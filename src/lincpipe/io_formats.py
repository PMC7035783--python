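"""Readers and writers for the standard formats the pipeline touches.

GTF (1-based inclusive) is converted to the internal 0-based half-open
convention at this boundary; BED6 is written natively. Tables are plain TSV.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .model import ExpressionMatrix, GenomicInterval, TranscriptModel, ValidationError


class ParseError(ValueError):
    """Raised on a malformed input line; the message names the file and line."""


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')
_NUC_RE = re.compile(r"^[ACGTN]*$")


def _parse_gtf_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(path: str | Path, biotype: str = "assembled_unknown") -> list[TranscriptModel]:
    """Read exon features from a GTF file into TranscriptModels.

    Exons are grouped by ``transcript_id`` and sorted by start; 1-based
    inclusive GTF coordinates become 0-based half-open. Transcripts whose
    lines disagree on strand are rejected; a missing strand (".") is kept
    as unknown. ``biotype`` tags every transcript from this file.
    """
    path = Path(path)
    exons: dict[str, list[GenomicInterval]] = {}
    gene_of: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated fields")
            if fields[2] != "exon":
                continue
            try:
                start1 = int(fields[3])
                end1 = int(fields[4])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start1 < 1 or end1 < start1:
                raise ParseError(f"{path}:{lineno}: bad coordinate range {start1}-{end1}")
            strand = fields[6]
            if strand not in ("+", "-", "."):
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            attrs = _parse_gtf_attributes(fields[8])
            tid = attrs.get("transcript_id")
            gid = attrs.get("gene_id")
            if not tid or not gid:
                raise ParseError(
                    f"{path}:{lineno}: exon line lacks transcript_id/gene_id"
                )
            iv = GenomicInterval(fields[0], start1 - 1, end1, strand)
            if tid not in exons:
                exons[tid] = []
                gene_of[tid] = gid
                order.append(tid)
            else:
                prev = exons[tid][0]
                if prev.chrom != iv.chrom:
                    raise ValidationError(f"{tid}: exons on multiple chromosomes")
                if prev.strand != iv.strand:
                    raise ValidationError(f"{tid}: exon lines disagree on strand")
            exons[tid].append(iv)

    transcripts = []
    for tid in order:
        exs = sorted(exons[tid], key=lambda e: e.start)
        transcripts.append(
            TranscriptModel(tid, gene_of[tid], tuple(exs), biotype=biotype)
        )
    return transcripts


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path,
              source: str = "lincpipe") -> None:
    """Write transcripts as GTF exon features (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for t in transcripts:
            for exon in t.exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{exon.chrom}\t{source}\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{exon.strand}\t.\t{attrs}\n"
                )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read nucleotide FASTA into {id: upper-cased sequence}.

    The id is the first whitespace-delimited token of the header. Duplicate
    ids and characters outside {A,C,G,T,N} are rejected.
    """
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ParseError(f"{path}: duplicate sequence id {record.id!r}")
        seq = str(record.seq).upper()
        if not _NUC_RE.match(seq):
            raise ParseError(
                f"{path}: record {record.id!r} contains non-nucleotide characters"
            )
        seqs[record.id] = seq
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a TSV with a header of condition names and first-column transcript ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name is None and df.shape[1] == 0 and df.shape[0] == 0:
        # header-only file: zero transcripts is legitimate
        pass
    if df.isna().to_numpy().any():
        raise ParseError(f"{path}: missing or ragged values in expression table")
    try:
        return ExpressionMatrix(df.astype(float))
    except (ValidationError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="transcript_id",
                       float_format="%.6g")


def write_bed(loci: Sequence[tuple[str, GenomicInterval]], path: str | Path) -> None:
    """Write named intervals as BED6; unknown strand becomes "."."""
    with open(path, "w") as fh:
        for name, iv in loci:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bed(path: str | Path) -> list[tuple[str, GenomicInterval]]:
    """Read BED (>= 3 columns) into named intervals; BED is already 0-based half-open."""
    loci = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            name = fields[3] if len(fields) > 3 else f"locus_{lineno}"
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in ("+", "-", "."):
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            loci.append((name, GenomicInterval(fields[0], int(fields[1]),
                                               int(fields[2]), strand)))
    return loci


def read_score_table(path: str | Path) -> dict[str, float]:
    """Read a two-column TSV (transcript_id, score), e.g. conservation scores."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected columns transcript_id, score")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


def read_domain_hits(path: str | Path) -> set[str]:
    """Read a domain-hit TSV (transcript_id, domain_accession, e_value).

    Any recorded hit counts as a hit; e-values are carried in the file so a
    caller may pre-filter rows before handing the table to the pipeline.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[0] == 0:
        return set()
    return set(df.iloc[:, 0].astype(str))


def read_go_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column TSV (gene_id, term_id) into gene -> set of terms."""
    df = pd.read_csv(path, sep="\t")
    mapping: dict[str, set[str]] = {}
    for gene, term in zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)):
        mapping.setdefault(gene, set()).add(term)
    return mapping


def read_go_terms(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read term metadata TSV (term_id, category, name) -> {term: (category, name)}."""
    df = pd.read_csv(path, sep="\t")
    return {
        str(t): (str(c), str(n))
        for t, c, n in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2])
    }
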