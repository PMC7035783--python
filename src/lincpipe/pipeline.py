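"""End-to-end orchestration: identify lincRNAs, then characterize them.

``run_identify`` executes the filter cascade — class-code assignment against
the reference annotation, selection of multi-exon intergenic ("u")
transcripts, and the four noncoding filters (logistic coding-potential score,
conservation rule, domain rule, maximal-ORF rule) — and emits the final
lincRNA set with a Table-style run report. ``run_characterize`` then scores
tissue specificity, compares the catalogue against external lncRNA sets, and
predicts cis-regulatory neighbor links with GO enrichment.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
import numpy as np

from . import __version__, io_formats
from . import classify as classify_mod
from . import catalogue_compare, cis_neighbors, tissue_specificity
from . import coding_potential as coding_mod
from .model import ExpressionMatrix, TranscriptModel, gene_spans

log = logging.getLogger("lincpipe")


@dataclass
class RunConfig:
    """Resolved inputs and thresholds for a pipeline run.

    ``cpat_cutoff`` is either "train" (derive the cutoff from the training
    sets by two-graph ROC) or a fixed probability such as the bovine-study
    constant 0.348, which only transfers to runs using that study's training
    data.
    """

    reference_coding_gtf: str = ""
    reference_smallrna_gtf: str = ""
    assembled_gtf: str = ""
    transcript_fasta: str = ""
    train_coding_fasta: str = ""
    train_noncoding_fasta: str = ""
    model_json: str = ""
    conservation_tsv: str = ""
    domain_tsv: str = ""
    linc_expression_tsv: str = ""
    gene_expression_tsv: str = ""
    go_map_tsv: str = ""
    go_terms_tsv: str = ""
    catalogue_beds: list[str] = field(default_factory=list)
    out_dir: str = "lincpipe_out"
    max_orf_aa: int = 100
    cpat_cutoff: str | float = "train"
    js_cutoff: float = 0.5
    neighbor_window: int = 50_000
    pcc_threshold: float = 0.9
    run_on_distance: int = 2000
    min_overlap_bp: int = 1
    fdr: float = 0.05
    held_out_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.js_cutoff < 1:
            raise ValueError("js_cutoff must be in (0, 1)")
        if not 0 < self.pcc_threshold <= 1:
            raise ValueError("pcc_threshold must be in (0, 1]")
        if self.max_orf_aa < 1 or self.neighbor_window < 0 or self.run_on_distance < 0:
            raise ValueError("thresholds out of range")
        if not 0 < self.fdr < 1 or self.min_overlap_bp < 1:
            raise ValueError("thresholds out of range")
        if isinstance(self.cpat_cutoff, str) and self.cpat_cutoff != "train":
            raise ValueError('cpat_cutoff must be "train" or a probability')
        if isinstance(self.cpat_cutoff, float) and not 0 < self.cpat_cutoff < 1:
            raise ValueError("cpat_cutoff must lie in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def mapping_summary(
    n_raw_reads: int, n_clean_reads: int, n_mapped_reads: int, n_concordant: int
) -> dict:
    """Read-accounting percentages for the sequencing section of the report.

    Each downstream count is expressed as a percentage of its denominator
    (clean of raw, mapped of clean, concordant of mapped), rounded to the
    nearest integer as conventionally printed.
    """
    def pct(num: int, den: int) -> float:
        return 100.0 * num / den if den else 0.0

    return {
        "n_raw_reads": n_raw_reads,
        "n_clean_reads": n_clean_reads,
        "n_mapped_reads": n_mapped_reads,
        "n_concordant": n_concordant,
        "clean_pct": round(pct(n_clean_reads, n_raw_reads)),
        "mapped_pct": round(pct(n_mapped_reads, n_clean_reads)),
        "concordant_pct": round(pct(n_concordant, n_mapped_reads)),
    }


def group_loci(transcripts: list[TranscriptModel]) -> list[list[str]]:
    """Single-linkage grouping of same-strand, span-overlapping transcripts.

    Each connected component is one genomic locus ("gene") of the final
    lincRNA set. Unknown-strand transcripts only group with each other.
    """
    n = len(transcripts)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    order = sorted(range(n), key=lambda i: (transcripts[i].chrom,
                                            transcripts[i].interval.start))
    for a in range(len(order)):
        i = order[a]
        si = transcripts[i].interval
        for b in range(a + 1, len(order)):
            j = order[b]
            sj = transcripts[j].interval
            if sj.chrom != si.chrom or sj.start >= si.end:
                break
            if transcripts[i].strand == transcripts[j].strand:
                union(i, j)
    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(transcripts[i].transcript_id)
    return sorted(groups.values())


def summarize(final: list[TranscriptModel]) -> dict:
    """Length/exon statistics and per-chromosome tally of the final set.

    Transcript length is spliced (exonic) length, not genomic span; the
    spread statistics are sample standard deviations. An empty set yields a
    zero report without statistics.
    """
    if not final:
        return {"n_transcripts": 0, "n_loci": 0, "per_chromosome": {}}
    lengths = np.array([t.spliced_length for t in final], dtype=float)
    exon_counts = np.array([len(t.exons) for t in final], dtype=float)
    per_chrom: dict[str, int] = {}
    for t in final:
        per_chrom[t.chrom] = per_chrom.get(t.chrom, 0) + 1
    ddof = 1 if len(final) > 1 else 0
    return {
        "n_transcripts": len(final),
        "n_loci": len(group_loci(final)),
        "mean_length": float(lengths.mean()),
        "sd_length": float(lengths.std(ddof=ddof)),
        "mean_exons": float(exon_counts.mean()),
        "sd_exons": float(exon_counts.std(ddof=ddof)),
        "per_chromosome": dict(sorted(per_chrom.items())),
    }


def _require(path: str, label: str) -> str:
    if not path or not Path(path).exists():
        raise FileNotFoundError(f"missing required input: {label} ({path!r})")
    return path


def _obtain_model(config: RunConfig) -> coding_mod.CodingModel:
    if config.model_json:
        model = coding_mod.CodingModel.load(_require(config.model_json, "model_json"))
    else:
        coding = io_formats.read_fasta(
            _require(config.train_coding_fasta, "train_coding_fasta"))
        noncoding = io_formats.read_fasta(
            _require(config.train_noncoding_fasta, "train_noncoding_fasta"))
        model = coding_mod.fit_coding_model(
            list(coding.values()), list(noncoding.values()),
            held_out_fraction=config.held_out_fraction, seed=config.seed)
    if isinstance(config.cpat_cutoff, float):
        model.cutoff = config.cpat_cutoff
    return model


def run_identify(
    config: RunConfig,
) -> tuple[list[TranscriptModel], dict]:
    """Execute classify -> candidate selection -> noncoding filter cascade.

    Writes the classification TSV, class summary, per-transcript filter
    results, the final lincRNA GTF and a JSON report into ``config.out_dir``.
    Returns (final transcripts, report).
    """
    _require(config.assembled_gtf, "assembled_gtf")
    _require(config.reference_coding_gtf, "reference_coding_gtf")
    _require(config.transcript_fasta, "transcript_fasta")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    refs = io_formats.read_gtf(config.reference_coding_gtf, biotype="protein_coding")
    if config.reference_smallrna_gtf:
        refs += io_formats.read_gtf(
            _require(config.reference_smallrna_gtf, "reference_smallrna_gtf"),
            biotype="small_rna")
    assembled = io_formats.read_gtf(config.assembled_gtf)
    sequences = io_formats.read_fasta(config.transcript_fasta)
    log.info("identify: %d assembled transcripts vs %d references",
             len(assembled), len(refs))

    coded = classify_mod.classify_all(assembled, refs, config.run_on_distance)
    class_summary = classify_mod.summarize_classes(coded)
    with open(out / "classification.tsv", "w") as fh:
        fh.write("transcript_id\tclass_code\tbest_reference\n")
        for c in coded:
            fh.write(f"{c.transcript.transcript_id}\t{c.code}\t{c.best_reference}\n")
    with open(out / "class_summary.tsv", "w") as fh:
        fh.write("class_code\tcount\n")
        for code, count in class_summary.items():
            fh.write(f"{code}\t{count}\n")

    candidates = classify_mod.select_candidates(coded)
    log.info("identify: %d multi-exon 'u' candidates", len(candidates))

    model = _obtain_model(config)
    model.save(out / "coding_model.json")
    conservation = (io_formats.read_score_table(config.conservation_tsv)
                    if config.conservation_tsv else None)
    domain_hits = (io_formats.read_domain_hits(config.domain_tsv)
                   if config.domain_tsv else None)

    results: list[coding_mod.CodingPotentialResult] = []
    final: list[TranscriptModel] = []
    for t in candidates:
        if t.transcript_id not in sequences:
            raise KeyError(f"candidate {t.transcript_id} missing from FASTA")
        res = coding_mod.apply_noncoding_filters(
            t.transcript_id, sequences[t.transcript_id], model,
            conservation, domain_hits, config.max_orf_aa)
        results.append(res)
        if res.is_noncoding_call:
            final.append(t)
    with open(out / "coding_results.tsv", "w") as fh:
        fh.write("transcript_id\torf_nt_length\torf_coverage\tfickett_score\t"
                 "hexamer_score\tlogistic_probability\tconservation_score\t"
                 "domain_hit\tpasses_cpat\tpasses_conservation\tpasses_domain\t"
                 "passes_maxorf\tis_noncoding_call\n")
        for r in results:
            f = r.features
            cons = "" if r.conservation_score is None else f"{r.conservation_score:.4g}"
            hit = "" if r.domain_hit is None else str(r.domain_hit)
            fh.write(f"{r.transcript_id}\t{f.orf_nt_length}\t{f.orf_coverage:.4f}\t"
                     f"{f.fickett_score:.4f}\t{f.hexamer_score:.4f}\t"
                     f"{r.logistic_probability:.6f}\t{cons}\t{hit}\t"
                     f"{r.passes_cpat}\t{r.passes_conservation}\t"
                     f"{r.passes_domain}\t{r.passes_maxorf}\t"
                     f"{r.is_noncoding_call}\n")

    io_formats.write_gtf(final, out / "lincrna.gtf")
    catalogue_compare.LocusSet.from_transcripts("lincrna", final).to_bed(
        out / "lincrna.bed")

    stats = summarize(final)
    report = {
        "software_version": __version__,
        "config": config.to_dict(),
        "cutoff_used": model.cutoff,
        "counts": {
            "input_transcripts": len(assembled),
            "per_class": class_summary,
            "candidates_u_multi_exon": len(candidates),
            "pass_cpat": sum(r.passes_cpat for r in results),
            "pass_conservation": sum(r.passes_conservation for r in results),
            "pass_domain": sum(r.passes_domain for r in results),
            "pass_maxorf": sum(r.passes_maxorf for r in results),
            "final_lincrnas": len(final),
            "final_loci": stats["n_loci"],
        },
        "skipped": {
            "conservation_filter": config.conservation_tsv == "",
            "domain_filter": config.domain_tsv == "",
        },
        "summary": stats,
    }
    (out / "report_identify.json").write_text(json.dumps(report, indent=2,
                                                         sort_keys=True))
    return final, report


def run_characterize(config: RunConfig) -> dict:
    """Specificity scoring, catalogue comparison and cis-neighbor prediction.

    Requires a prior ``run_identify`` in the same ``out_dir`` (reads its
    lincrna.gtf). Optional stages without inputs are skipped with a notice.
    """
    out = Path(config.out_dir)
    final = io_formats.read_gtf(_require(str(out / "lincrna.gtf"), "lincrna.gtf"))
    expr = io_formats.read_expression_table(
        _require(config.linc_expression_tsv, "linc_expression_tsv"))

    missing = [t.transcript_id for t in final if t.transcript_id not in expr]
    if missing:
        log.warning("characterize: %d lincRNAs lack expression rows; excluded",
                    len(missing))
    kept = [t for t in final if t.transcript_id in expr]
    sub = ExpressionMatrix(expr.data.loc[[t.transcript_id for t in kept]])
    results, unscorable = tissue_specificity.score_matrix(sub, config.js_cutoff)
    specific, _, frac_one = tissue_specificity.call_specific(results,
                                                            config.js_cutoff)
    with open(out / "specificity.tsv", "w") as fh:
        fh.write("transcript_id\tjs_score\targmax_condition\tis_specific\n")
        for r in results:
            fh.write(f"{r.transcript_id}\t{r.js_score:.6f}\t"
                     f"{r.argmax_condition}\t{r.is_specific}\n")
    with open(out / "specificity_histogram.tsv", "w") as fh:
        fh.write("bin_start\tbin_end\tcount\n")
        for lo, hi, count in tissue_specificity.score_histogram(results):
            fh.write(f"{lo:.1f}\t{hi:.1f}\t{count}\n")

    report: dict = {
        "software_version": __version__,
        "config": config.to_dict(),
        "specificity": {
            "n_scored": len(results),
            "n_unscorable": len(unscorable),
            "n_missing_expression": len(missing),
            "n_specific": len(specific),
            "fraction_specific": len(specific) / len(results) if results else 0.0,
            "fraction_js_one": frac_one,
        },
        "skipped": [],
    }

    primary = catalogue_compare.LocusSet.from_transcripts("lincrna", kept)
    if config.catalogue_beds:
        others = [catalogue_compare.LocusSet.from_bed(p)
                  for p in config.catalogue_beds]
        membership, regions = catalogue_compare.multi_set_membership(
            primary, others, config.min_overlap_bp)
        with open(out / "catalogue_membership.tsv", "w") as fh:
            fh.write("locus\t" + "\t".join(o.name for o in others) + "\n")
            for name, flags in sorted(membership.items()):
                fh.write(name + "\t" + "\t".join(map(str, flags)) + "\n")
        report["catalogue_comparison"] = {
            "sets": [o.name for o in others],
            "unique_to_primary": regions.get(tuple([False] * len(others)), 0),
            "region_counts": {
                "|".join("1" if f else "0" for f in key): count
                for key, count in sorted(regions.items())
            },
        }
    else:
        log.info("characterize: no external catalogues supplied; comparison skipped")
        report["skipped"].append("catalogue_comparison")

    if config.gene_expression_tsv:
        gene_expr = io_formats.read_expression_table(config.gene_expression_tsv)
        refs = io_formats.read_gtf(config.reference_coding_gtf,
                                   biotype="protein_coding")
        spans = gene_spans(refs)
        specific_ids = {r.transcript_id for r in specific}
        specific_set = catalogue_compare.LocusSet.from_transcripts(
            "specific_lincrna", [t for t in kept if t.transcript_id in specific_ids])
        pairs = cis_neighbors.find_neighbors(specific_set, spans,
                                             config.neighbor_window)
        links, dropped = cis_neighbors.correlate(pairs, sub, gene_expr,
                                                 config.pcc_threshold)
        with open(out / "neighbor_links.tsv", "w") as fh:
            fh.write("lincrna_id\tgene_id\tdistance\tpcc\tstrong\n")
            for link in links:
                fh.write(f"{link.lincrna_id}\t{link.gene_id}\t{link.distance}\t"
                         f"{link.pcc:.6f}\t{link.strong}\n")
        strong_links = [l for l in links if l.strong]
        report["neighbors"] = {
            "n_specific_lincs": len(specific_set),
            "n_pairs": len(pairs),
            "n_links": len(links),
            "n_dropped": len(dropped),
            "n_strong_links": len(strong_links),
            "n_strong_lincs": len({l.lincrna_id for l in strong_links}),
            "n_strong_genes": len({l.gene_id for l in strong_links}),
            "pcc_threshold": config.pcc_threshold,
        }
        if config.go_map_tsv and strong_links:
            go_map = io_formats.read_go_map(config.go_map_tsv)
            meta = (io_formats.read_go_terms(config.go_terms_tsv)
                    if config.go_terms_tsv else None)
            background = set(gene_expr.transcript_ids)
            foreground = {l.gene_id for l in strong_links} & background
            enrichment = cis_neighbors.go_enrichment(foreground, background,
                                                     go_map, meta)
            with open(out / "go_enrichment.tsv", "w") as fh:
                fh.write("term_id\tcategory\tname\tk\tK\tn\tN\tp_value\tadjusted_p\n")
                for e in enrichment:
                    fh.write(f"{e.go_term_id}\t{e.category}\t{e.name}\t{e.k}\t"
                             f"{e.K}\t{e.n}\t{e.N}\t{e.p_value:.6g}\t"
                             f"{e.adjusted_p:.6g}\n")
            report["go_enrichment"] = {
                "n_terms_tested": len(enrichment),
                "n_significant": sum(e.adjusted_p <= config.fdr
                                     for e in enrichment),
                "fdr": config.fdr,
            }
        else:
            report["skipped"].append("go_enrichment")
    else:
        log.info("characterize: no gene expression supplied; neighbor "
                 "analysis skipped")
        report["skipped"].append("neighbors")
        report["skipped"].append("go_enrichment")

    (out / "report_characterize.json").write_text(
        json.dumps(report, indent=2, sort_keys=True))
    return report
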