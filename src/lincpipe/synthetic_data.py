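"""Seeded generators for every input the pipeline consumes.

The generators emit a toy genome annotation, assembled transcripts built by
explicit geometry to realize each class code, transcript and training
sequences with planted coding/noncoding structure, expression matrices with
planted specificity and neighbor-correlation patterns, and a GO map with a
planted enriched term. Every record carries ground truth, so closed-loop
tests (generate -> run a pipeline stage -> compare to truth) are possible.

Coding and noncoding sequence regimes differ in first-order composition
(GC-rich codon usage inside planted ORFs vs an AT-rich background Markov
chain), which makes the hexamer-bias feature informative without any real
genome data. The same seed always reproduces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from . import io_formats
from .coding_potential import find_max_orf, STOP_CODONS
from .model import ExpressionMatrix, GenomicInterval, TranscriptModel, gene_spans

BASES = "ACGT"

#: Background (noncoding) composition: AT-rich with a mild repeat bias.
_NONCODING_COMP = np.array([0.32, 0.18, 0.18, 0.32])
#: Base preferences inside planted coding ORFs: GC-rich.
_CODING_BASE_PROBS = np.array([0.18, 0.32, 0.32, 0.18])


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic dataset.

    Defaults are desk scale: 2 chromosomes x 2 Mb, ~60 reference genes,
    ~200 assembled transcripts spanning every class code, 10 conditions
    (oocyte + 9 tissues), and 500+500 training sequences.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_coding_genes: int = 50
    n_small_rnas: int = 10
    class_counts: dict = field(default_factory=lambda: {
        "=": 10, "c": 10, "j": 10, "e": 10, "i": 10,
        "o": 10, "p": 10, "u": 60, "x": 10, "s": 10,
    })
    u_single_exon_fraction: float = 0.25
    u_coding_fraction: float = 0.3
    coding_orf_aa_range: tuple[int, int] = (101, 299)   # ORF of 306..900 nt
    noncoding_max_orf_aa: int = 100
    n_train_coding: int = 500
    n_train_noncoding: int = 500
    n_conditions: int = 10
    frac_single: float = 0.4
    frac_few: float = 0.3
    # remainder of the specificity mix is ubiquitous
    n_correlated_pairs: int = 10
    correlation_noise_sd: float = 0.5
    spike_factor: float = 50.0
    n_go_terms: int = 20
    go_base_prob: float = 0.05
    go_planted_fold: float = 10.0
    run_on_distance: int = 2000

    @property
    def condition_names(self) -> list[str]:
        return ["oocyte"] + [f"tissue_{i}" for i in range(1, self.n_conditions)]


@dataclass
class GroundTruth:
    """Planted labels covering every emitted record."""

    class_code: dict[str, str] = field(default_factory=dict)
    coding_label: dict[str, str] = field(default_factory=dict)     # coding|noncoding
    specificity_class: dict[str, str] = field(default_factory=dict)
    specificity_condition: dict[str, str] = field(default_factory=dict)
    correlated_pairs: list[tuple[str, str]] = field(default_factory=list)
    planted_go_term: str = ""
    planted_go_enriched: bool = False


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    coding_refs: list[TranscriptModel]
    smallrna_refs: list[TranscriptModel]
    assembled: list[TranscriptModel]
    sequences: dict[str, str]
    train_coding: dict[str, str]
    train_noncoding: dict[str, str]
    conservation: dict[str, float]
    domain_hits: set[str]
    linc_expression: ExpressionMatrix
    gene_expression: ExpressionMatrix
    go_map: dict[str, set[str]]
    go_terms: dict[str, tuple[str, str]]
    truth: GroundTruth

    @property
    def references(self) -> list[TranscriptModel]:
        return self.coding_refs + self.smallrna_refs

    def expected_final_lincs(self) -> set[str]:
        """Transcripts that should survive the full identification cascade."""
        return {
            tid for tid, code in self.truth.class_code.items()
            if code == "u"
            and self.truth.coding_label.get(tid) == "noncoding"
        }


# ---------------------------------------------------------------------------
# sequence regimes
# ---------------------------------------------------------------------------

def _transition_cumsums() -> list[tuple[float, float, float]]:
    rows = []
    for cur in range(4):
        trans = 0.75 * _NONCODING_COMP
        trans[cur] += 0.25
        c = np.cumsum(trans)
        rows.append((float(c[0]), float(c[1]), float(c[2])))
    return rows


_NONCODING_CUMS = _transition_cumsums()
_INIT_CUM = tuple(np.cumsum(_NONCODING_COMP)[:3].tolist())


def _markov_background(rng: np.random.Generator, length: int) -> str:
    """AT-rich first-order Markov sequence (25% self-transition bias)."""
    if length <= 0:
        return ""
    us = rng.random(length)
    u0 = us[0]
    c0, c1, c2 = _INIT_CUM
    cur = 0 if u0 < c0 else 1 if u0 < c1 else 2 if u0 < c2 else 3
    out = [BASES[cur]]
    for u in us[1:]:
        c0, c1, c2 = _NONCODING_CUMS[cur]
        cur = 0 if u < c0 else 1 if u < c1 else 2 if u < c2 else 3
        out.append(BASES[cur])
    return "".join(out)


def _coding_codons(rng: np.random.Generator, n_codons: int) -> str:
    """Sense codons drawn from the GC-rich coding regime (stops excluded)."""
    codons: list[str] = []
    while len(codons) < n_codons:
        need = n_codons - len(codons)
        draw = rng.choice(4, size=3 * (need + 8), p=_CODING_BASE_PROBS)
        for j in range(0, len(draw) - 2, 3):
            codon = BASES[draw[j]] + BASES[draw[j + 1]] + BASES[draw[j + 2]]
            if codon not in STOP_CODONS:
                codons.append(codon)
                if len(codons) == n_codons:
                    break
    return "".join(codons)


def _cds(rng: np.random.Generator, aa_length: int) -> str:
    """ATG + (aa_length - 1) sense codons + stop; in frame from position 0."""
    stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    return "ATG" + _coding_codons(rng, aa_length - 1) + stop


def _noncoding_sequence(
    rng: np.random.Generator, length: int, max_orf_aa: int, retries: int = 100
) -> str:
    for _ in range(retries):
        seq = _markov_background(rng, length)
        if find_max_orf(seq).aa_length <= max_orf_aa:
            return seq
    raise RuntimeError("rejection sampling budget exceeded for noncoding sequence")


def _coding_sequence(
    rng: np.random.Generator, length: int, aa_range: tuple[int, int]
) -> str:
    """Background sequence with an embedded in-frame ORF from the coding regime."""
    lo, hi = aa_range
    hi = min(hi, (length - 40) // 3 - 2)
    if hi < lo:
        raise ValueError(f"sequence length {length} too short for ORF of >= {lo} aa")
    aa = int(rng.integers(lo, hi + 1))
    cds = _cds(rng, aa)
    utr5_len = int(rng.integers(5, max(6, length - len(cds) - 5)))
    utr5 = _markov_background(rng, utr5_len)
    utr3 = _markov_background(rng, length - len(cds) - utr5_len)
    return utr5 + cds + utr3


def generate_training_sequences(
    cfg: SyntheticConfig, rng: np.random.Generator
) -> tuple[dict[str, str], dict[str, str]]:
    """Labelled training sets: pure CDS vs capped-ORF background sequences."""
    coding = {
        f"cds.{i}": _cds(rng, int(rng.integers(*cfg.coding_orf_aa_range)))
        for i in range(cfg.n_train_coding)
    }
    noncoding = {
        f"nc.{i}": _noncoding_sequence(
            rng, int(rng.integers(300, 1501)), cfg.noncoding_max_orf_aa
        )
        for i in range(cfg.n_train_noncoding)
    }
    return coding, noncoding


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(
    cfg: SyntheticConfig, rng: np.random.Generator
) -> tuple[list[TranscriptModel], list[TranscriptModel], list[tuple[str, int]]]:
    """Non-overlapping reference genes on evenly spaced anchors.

    Returns (coding refs, small-RNA refs, desert centers) where deserts are
    intergenic points far (>> run-on distance) from every reference, reserved
    for "u" placements.
    """
    total = cfg.n_coding_genes + cfg.n_small_rnas
    per_chrom = int(np.ceil(total / cfg.n_chroms))
    spacing = cfg.chrom_length // (per_chrom + 1)
    if spacing < 30_000:
        raise ValueError("chromosome too short for requested gene count")
    coding: list[TranscriptModel] = []
    small: list[TranscriptModel] = []
    deserts: list[tuple[str, int]] = []
    for g in range(total):
        chrom = f"chr{g % cfg.n_chroms + 1}"
        slot = g // cfg.n_chroms
        anchor = spacing * (slot + 1) + int(rng.integers(0, 2000))
        strand = "+" if rng.random() < 0.5 else "-"
        if g < cfg.n_coding_genes:
            n_exons = int(rng.integers(3, 8))
            exons = []
            pos = anchor
            for _ in range(n_exons):
                exon_len = int(rng.integers(150, 301))
                exons.append(GenomicInterval(chrom, pos, pos + exon_len, strand))
                pos += exon_len + int(rng.integers(300, 1501))
            gid = f"gene.{g}"
            coding.append(TranscriptModel(
                f"{gid}.t1", gid, tuple(exons), biotype="protein_coding"))
        else:
            length = int(rng.integers(70, 151))
            gid = f"srna.{g}"
            small.append(TranscriptModel(
                f"{gid}.t1", gid,
                (GenomicInterval(chrom, anchor, anchor + length, strand),),
                biotype="small_rna"))
        # desert midway to the next anchor: >= ~20 kb from any reference
        deserts.append((chrom, anchor + int(spacing * 0.6)))
    return coding, small, deserts


# ---------------------------------------------------------------------------
# assembled transcripts with planted class codes
# ---------------------------------------------------------------------------

def _jitter_match(ref: TranscriptModel, rng) -> tuple[GenomicInterval, ...]:
    """Copy of the reference exon chain with jittered terminal exon ends."""
    exons = list(ref.exons)
    first, last = exons[0], exons[-1]
    d1 = int(rng.integers(0, min(50, len(first) - 10)))
    d2 = int(rng.integers(0, min(50, len(last) - 10)))
    exons[0] = GenomicInterval(first.chrom, first.start + d1, first.end, first.strand)
    exons[-1] = GenomicInterval(last.chrom, last.start, last.end - d2, last.strand)
    return tuple(exons)


def _make_for_class(
    code: str, ref: TranscriptModel, rng: np.random.Generator
) -> tuple[GenomicInterval, ...] | None:
    chrom, strand = ref.chrom, ref.strand
    span = ref.interval
    if code == "=":
        return _jitter_match(ref, rng)
    if code == "c":
        inner = list(ref.exons[1:-1])
        if len(inner) == 1:
            e = inner[0]
            return (GenomicInterval(chrom, e.start + 10, e.end - 10, strand),)
        return tuple(inner)
    if code == "j":
        # shift one internal acceptor 30 bp into the upstream intron; the
        # remaining junctions stay shared, so the chains differ but overlap
        exons = list(ref.exons)
        e1 = exons[1]
        exons[1] = GenomicInterval(chrom, e1.start - 30, e1.end, strand)
        return tuple(exons)
    if code == "e":
        fe = ref.exons[0]
        return (GenomicInterval(chrom, fe.end - 60, fe.end + 50, strand),)
    if code == "i":
        istart, iend = ref.introns[0]
        if iend - istart < 160:
            return None
        return (GenomicInterval(chrom, istart + 50, iend - 50, strand),)
    if code == "o":
        fe = ref.exons[0]
        if fe.start < 700:
            return None
        return (
            GenomicInterval(chrom, fe.start - 600, fe.start - 400, strand),
            GenomicInterval(chrom, fe.start - 150, fe.start + 50, strand),
        )
    if code == "p":
        if strand == "+":
            pos = span.end + 400
        else:
            pos = span.start - 800
        if pos < 0:
            return None
        return (GenomicInterval(chrom, pos, pos + 400, strand),)
    if code == "x":
        fe = ref.exons[0]
        flipped = "-" if strand == "+" else "+"
        return (GenomicInterval(chrom, fe.start + 10, fe.end - 10, flipped),)
    if code == "s":
        istart, iend = ref.introns[0]
        flipped = "-" if strand == "+" else "+"
        if iend - istart < 160:
            return None
        return (GenomicInterval(chrom, istart + 50, iend - 50, flipped),)
    raise ValueError(f"cannot construct class {code!r}")


def _make_u_exons(
    chrom: str, center: int, rng: np.random.Generator,
    multi_exon: bool, coding_label: bool,
) -> tuple[GenomicInterval, ...]:
    strand = "+" if rng.random() < 0.5 else "-"
    if not multi_exon:
        length = int(rng.integers(300, 801))
        return (GenomicInterval(chrom, center, center + length, strand),)
    if coding_label:
        n_exons, lo, hi = 3, 350, 501
    else:
        n_exons, lo, hi = int(rng.integers(2, 5)), 150, 401
    exons = []
    pos = center
    for _ in range(n_exons):
        exon_len = int(rng.integers(lo, hi))
        exons.append(GenomicInterval(chrom, pos, pos + exon_len, strand))
        pos += exon_len + int(rng.integers(200, 801))
    return tuple(exons)


def generate_assembled(
    cfg: SyntheticConfig,
    coding_refs: list[TranscriptModel],
    deserts: list[tuple[str, int]],
    rng: np.random.Generator,
) -> tuple[list[TranscriptModel], GroundTruth]:
    """Assembled transcripts constructed to realize each requested class code."""
    multi_refs = [r for r in coding_refs if r.is_multi_exon]
    anchored = sum(cfg.class_counts.get(c, 0)
                   for c in ("=", "c", "j", "e", "i", "o", "p", "x", "s"))
    if anchored and not multi_refs:
        raise ValueError("class construction needs multi-exon references")
    truth = GroundTruth()
    out: list[TranscriptModel] = []
    counter = 0
    ref_cursor = 0
    for code in ("=", "c", "j", "e", "i", "o", "p", "x", "s"):
        want = cfg.class_counts.get(code, 0)
        made = 0
        attempts = 0
        while made < want:
            if attempts > want * len(multi_refs) + 10:
                raise ValueError(f"cannot place {want} transcripts of class {code!r}")
            ref = multi_refs[ref_cursor % len(multi_refs)]
            ref_cursor += 1
            attempts += 1
            exons = _make_for_class(code, ref, rng)
            if exons is None:
                continue
            tid = f"asm.{counter}"
            counter += 1
            out.append(TranscriptModel(tid, f"asmgene.{tid}", exons))
            truth.class_code[tid] = code
            made += 1

    n_u = cfg.class_counts.get("u", 0)
    n_u_single = int(round(n_u * cfg.u_single_exon_fraction))
    n_u_multi = n_u - n_u_single
    n_u_coding = int(round(n_u_multi * cfg.u_coding_fraction))
    if n_u > 4 * len(deserts):
        raise ValueError("not enough intergenic room for requested 'u' transcripts")
    slot_of = [(i % len(deserts), i // len(deserts)) for i in range(n_u)]
    for i in range(n_u):
        desert_i, sub = slot_of[i]
        chrom, center = deserts[desert_i]
        center = center + sub * 5000
        multi = i >= n_u_single
        coding_label = multi and (i - n_u_single) < n_u_coding
        exons = _make_u_exons(chrom, center, rng, multi, coding_label)
        tid = f"asm.{counter}"
        counter += 1
        out.append(TranscriptModel(tid, f"asmgene.{tid}", exons))
        truth.class_code[tid] = "u"
        if multi:
            truth.coding_label[tid] = "coding" if coding_label else "noncoding"
    return out, truth


# ---------------------------------------------------------------------------
# sequences, scores, expression, GO
# ---------------------------------------------------------------------------

def generate_sequences(
    cfg: SyntheticConfig,
    assembled: list[TranscriptModel],
    truth: GroundTruth,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Per-transcript nucleotide sequences matching each spliced length.

    Coding-labelled transcripts embed an in-frame ORF from the coding regime;
    every other transcript draws from the capped background regime.
    """
    seqs: dict[str, str] = {}
    for t in assembled:
        length = t.spliced_length
        if truth.coding_label.get(t.transcript_id) == "coding":
            seqs[t.transcript_id] = _coding_sequence(rng, length, cfg.coding_orf_aa_range)
        else:
            seqs[t.transcript_id] = _noncoding_sequence(
                rng, length, cfg.noncoding_max_orf_aa)
    return seqs


def generate_score_tables(
    assembled: list[TranscriptModel],
    truth: GroundTruth,
    rng: np.random.Generator,
) -> tuple[dict[str, float], set[str]]:
    """Conservation scores and domain hits consistent with the coding labels.

    Coding-labelled transcripts get positive conservation scores and a domain
    hit; all others get negative scores and no hit.
    """
    conservation: dict[str, float] = {}
    hits: set[str] = set()
    for t in assembled:
        tid = t.transcript_id
        if truth.coding_label.get(tid) == "coding":
            conservation[tid] = float(np.round(rng.uniform(10, 100), 3))
            hits.add(tid)
        else:
            conservation[tid] = float(np.round(-rng.uniform(10, 100), 3))
    return conservation, hits


def generate_expression(
    cfg: SyntheticConfig,
    assembled: list[TranscriptModel],
    coding_refs: list[TranscriptModel],
    truth: GroundTruth,
    rng: np.random.Generator,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """FPKM matrices with planted specificity and neighbor-correlation patterns.

    Final-linc candidates are split into correlated/spiky, single-condition,
    few-condition and ubiquitous classes per the configured mix; correlated
    pairs share a latent positive factor plus half-normal noise.
    """
    conditions = cfg.condition_names
    n_cond = len(conditions)
    spans = gene_spans(coding_refs)
    gene_ids = sorted(spans)

    linc_rows: dict[str, np.ndarray] = {}
    gene_rows: dict[str, np.ndarray] = {
        gid: rng.uniform(1, 50, size=n_cond) for gid in gene_ids
    }

    finals = sorted(t.transcript_id for t in assembled
                    if t.transcript_id in truth.coding_label
                    and truth.coding_label[t.transcript_id] == "noncoding")
    by_id = {t.transcript_id: t for t in assembled}

    # correlated pairs first: each needs a protein-coding neighbor within 50 kb
    n_corr = 0
    used_genes: set[str] = set()
    for tid in finals:
        if n_corr >= cfg.n_correlated_pairs:
            break
        span = by_id[tid].interval
        partner = None
        best_d = None
        for gid in gene_ids:
            g = spans[gid]
            if g.chrom != span.chrom or gid in used_genes:
                continue
            d = span.distance_to(g)
            if d <= 50_000 and (best_d is None or d < best_d):
                partner, best_d = gid, d
        if partner is None:
            continue
        cond = int(rng.integers(n_cond))
        factor = rng.uniform(1, 3, size=n_cond)
        factor[cond] *= cfg.spike_factor
        linc_rows[tid] = factor * rng.uniform(1, 2)
        gene_rows[partner] = factor * rng.uniform(1, 2) + np.abs(
            rng.normal(0, cfg.correlation_noise_sd, size=n_cond))
        truth.correlated_pairs.append((tid, partner))
        truth.specificity_class[tid] = "spiky"
        truth.specificity_condition[tid] = conditions[cond]
        used_genes.add(partner)
        n_corr += 1

    remaining = [tid for tid in finals if tid not in linc_rows]
    n_single = int(round(len(remaining) * cfg.frac_single))
    n_few = int(round(len(remaining) * cfg.frac_few))
    for idx, tid in enumerate(remaining):
        row = np.zeros(n_cond)
        if idx < n_single:
            cond = int(rng.integers(n_cond))
            row[cond] = rng.uniform(10, 100)
            truth.specificity_class[tid] = "single"
            truth.specificity_condition[tid] = conditions[cond]
        elif idx < n_single + n_few:
            picks = rng.choice(n_cond, size=int(rng.integers(2, 4)), replace=False)
            row[picks] = rng.uniform(10, 100, size=picks.size)
            truth.specificity_class[tid] = "few"
            truth.specificity_condition[tid] = conditions[int(picks[0])]
        else:
            row = rng.uniform(5, 10, size=n_cond)
            truth.specificity_class[tid] = "ubiquitous"
            truth.specificity_condition[tid] = ""
        linc_rows[tid] = row

    # everything else assembled: unremarkable broad expression
    for t in assembled:
        if t.transcript_id not in linc_rows:
            linc_rows[t.transcript_id] = rng.uniform(1, 20, size=n_cond)

    ids = [t.transcript_id for t in assembled]
    linc_values = (np.vstack([np.round(linc_rows[i], 4) for i in ids])
                   if ids else np.empty((0, n_cond)))
    gene_values = (np.vstack([np.round(gene_rows[g], 4) for g in gene_ids])
                   if gene_ids else np.empty((0, n_cond)))
    linc = ExpressionMatrix.from_arrays(ids, conditions, linc_values)
    gene = ExpressionMatrix.from_arrays(gene_ids, conditions, gene_values)
    return linc, gene


def generate_go(
    cfg: SyntheticConfig,
    background_genes: list[str],
    foreground_genes: list[str],
    rng: np.random.Generator,
) -> tuple[dict[str, set[str]], dict[str, tuple[str, str]], str]:
    """GO map with uniform background term frequencies and one planted term.

    The planted term (first BP term) is assigned to foreground genes at
    ``go_planted_fold`` times the background probability; fold 1.0 is the
    null (type-I control) configuration.
    """
    terms = [f"GO:{i + 1:07d}" for i in range(cfg.n_go_terms)]
    categories = {t: ("BP", "MF", "CC")[i % 3] for i, t in enumerate(terms)}
    planted = terms[0]
    fg = set(foreground_genes)
    go_map: dict[str, set[str]] = {}
    for gene in sorted(background_genes):
        assigned = set()
        for term in terms:
            p = cfg.go_base_prob
            if term == planted and gene in fg:
                p = min(1.0, cfg.go_planted_fold * cfg.go_base_prob)
            if rng.random() < p:
                assigned.add(term)
        if assigned:
            go_map[gene] = assigned
    meta = {t: (categories[t], f"synthetic term {t}") for t in terms}
    return go_map, meta, planted


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate the full dataset in memory, deterministically under cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    coding_refs, smallrna_refs, deserts = generate_annotation(cfg, rng)
    assembled, truth = generate_assembled(cfg, coding_refs, deserts, rng)
    sequences = generate_sequences(cfg, assembled, truth, rng)
    train_coding, train_noncoding = generate_training_sequences(cfg, rng)
    conservation, hits = generate_score_tables(assembled, truth, rng)
    linc_expr, gene_expr = generate_expression(
        cfg, assembled, coding_refs, truth, rng)
    foreground = sorted(g for _, g in truth.correlated_pairs)
    go_map, go_terms, planted = generate_go(
        cfg, gene_expr.transcript_ids, foreground, rng)
    truth.planted_go_term = planted
    truth.planted_go_enriched = cfg.go_planted_fold > 1.0
    return SyntheticDataset(
        config=cfg,
        coding_refs=coding_refs,
        smallrna_refs=smallrna_refs,
        assembled=assembled,
        sequences=sequences,
        train_coding=train_coding,
        train_noncoding=train_noncoding,
        conservation=conservation,
        domain_hits=hits,
        linc_expression=linc_expr,
        gene_expression=gene_expr,
        go_map=go_map,
        go_terms=go_terms,
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, str]:
    """Write every input file the pipeline reads, plus ground-truth TSVs.

    Returns a manifest of file paths (also saved as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = {
        "reference_coding_gtf": "reference_coding.gtf",
        "reference_smallrna_gtf": "reference_smallrna.gtf",
        "assembled_gtf": "assembled.gtf",
        "transcript_fasta": "transcripts.fa",
        "train_coding_fasta": "train_coding.fa",
        "train_noncoding_fasta": "train_noncoding.fa",
        "conservation_tsv": "conservation.tsv",
        "domain_tsv": "domain_hits.tsv",
        "linc_expression_tsv": "linc_expression.tsv",
        "gene_expression_tsv": "gene_expression.tsv",
        "go_map_tsv": "go_map.tsv",
        "go_terms_tsv": "go_terms.tsv",
    }
    paths = {k: str(out / v) for k, v in names.items()}
    io_formats.write_gtf(ds.coding_refs, paths["reference_coding_gtf"])
    io_formats.write_gtf(ds.smallrna_refs, paths["reference_smallrna_gtf"])
    io_formats.write_gtf(ds.assembled, paths["assembled_gtf"])
    io_formats.write_fasta(ds.sequences, paths["transcript_fasta"])
    io_formats.write_fasta(ds.train_coding, paths["train_coding_fasta"])
    io_formats.write_fasta(ds.train_noncoding, paths["train_noncoding_fasta"])
    with open(paths["conservation_tsv"], "w") as fh:
        fh.write("transcript_id\tscore\n")
        for tid in sorted(ds.conservation):
            fh.write(f"{tid}\t{ds.conservation[tid]}\n")
    with open(paths["domain_tsv"], "w") as fh:
        fh.write("transcript_id\tdomain_accession\te_value\n")
        for tid in sorted(ds.domain_hits):
            fh.write(f"{tid}\tPF00001\t1e-10\n")
    io_formats.write_expression_table(ds.linc_expression,
                                      paths["linc_expression_tsv"])
    io_formats.write_expression_table(ds.gene_expression,
                                      paths["gene_expression_tsv"])
    with open(paths["go_map_tsv"], "w") as fh:
        fh.write("gene_id\tterm_id\n")
        for gene in sorted(ds.go_map):
            for term in sorted(ds.go_map[gene]):
                fh.write(f"{gene}\t{term}\n")
    with open(paths["go_terms_tsv"], "w") as fh:
        fh.write("term_id\tcategory\tname\n")
        for term in sorted(ds.go_terms):
            cat, name = ds.go_terms[term]
            fh.write(f"{term}\t{cat}\t{name}\n")

    truth = ds.truth
    with open(out / "truth_classes.tsv", "w") as fh:
        fh.write("transcript_id\tclass_code\tcoding_label\n")
        for tid in sorted(truth.class_code):
            fh.write(f"{tid}\t{truth.class_code[tid]}\t"
                     f"{truth.coding_label.get(tid, '')}\n")
    with open(out / "truth_specificity.tsv", "w") as fh:
        fh.write("transcript_id\tclass\tcondition\n")
        for tid in sorted(truth.specificity_class):
            fh.write(f"{tid}\t{truth.specificity_class[tid]}\t"
                     f"{truth.specificity_condition.get(tid, '')}\n")
    with open(out / "truth_pairs.tsv", "w") as fh:
        fh.write("lincrna_id\tgene_id\n")
        for linc, gene in sorted(truth.correlated_pairs):
            fh.write(f"{linc}\t{gene}\n")
    with open(out / "truth_go.tsv", "w") as fh:
        fh.write("planted_term\tenriched\n")
        fh.write(f"{truth.planted_go_term}\t{truth.planted_go_enriched}\n")

    # manifest paths are relative to out_dir so identically seeded runs in
    # different directories stay byte-identical
    manifest = dict(names)
    manifest["seed"] = ds.config.seed
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths


def load_manifest(out_dir: str | Path) -> tuple[dict[str, str], int]:
    """Resolve a written dataset's manifest to absolute input paths.

    Returns (path mapping keyed like RunConfig fields, seed).
    """
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    seed = int(manifest.pop("seed"))
    return {k: str(out / v) for k, v in manifest.items()}, seed


def simulate(cfg: SyntheticConfig, out_dir: str | Path) -> SyntheticDataset:
    """Generate and write the full synthetic dataset."""
    ds = generate_dataset(cfg)
    write_dataset(ds, out_dir)
    return ds
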