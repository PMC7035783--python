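# Methods

## Coordinate and data model

All internal coordinates are 0-based half-open; GTF I/O (1-based inclusive)
converts at the boundary and BED is written natively. A transcript is an
ordered tuple of non-overlapping exons sharing one chromosome and strand;
its intron chain is the tuple of (donor, acceptor) coordinate pairs.
Transcripts whose GTF exon lines disagree on strand are rejected rather than
repaired; a missing strand is carried as unknown. Transcript "length"
everywhere means spliced (exonic) length, not genomic span, and spread
statistics are sample standard deviations.

## Class-code assignment

Each assembled transcript is compared to every reference transcript whose
span lies within its span extended by the run-on distance. Per reference,
one code is derived from explicit geometry:

- `=` — identical intron chains (both multi-exon, same known strand).
- `c` — every exon contained in a reference exon, every intron present in
  the reference chain, and strictly fewer exons (so `=` and `c` are
  disjoint).
- `j` — at least one shared intron but different chains (same known strand).
  Junction sharing is evaluated at the whole-intron level (both splice
  sites), which is the stricter reading.
- `e` — single-exon transcript overlapping a reference exon and reaching
  ≥ 10 bp into a reference intron.
- `i` / `s` — span entirely inside a reference intron, same / opposite
  strand.
- `o` / `x` — other exonic overlap, same / opposite strand.
- `p` — no exonic overlap, span starting within the run-on distance
  (default 2,000 bp, configurable) downstream of a same-strand reference
  3′ end.
- `u` — none of the above against any reference.

When several references yield codes, the most specific wins in the fixed
order `=` > `c` > `j` > `e` > `o` > `i` > `x` > `s` > `p`; remaining ties go
to the reference with the larger exonic overlap in bp, then the
lexicographically smaller id. The precedence and tie-breaks make
classification deterministic; assemblers' own tools do not document theirs.
Strand-unknown transcripts are compared against both strands but are never
eligible for `=`, `j`, `x` or `s`, all of which require orientation. The
candidate pool for lincRNA identification is the multi-exon `u` set.

## Coding-potential model

Features per sequence (forward strand only — assembled transcripts are
already oriented):

- **Maximal ORF length** (nt). ORFs start at ATG and end at the first
  in-frame stop; the stop codon is counted in the nt length but not in the
  amino-acid length. ORFs without an in-frame stop are allowed (truncated
  transcripts) and run to the last complete codon. Codons containing N never
  match ATG or a stop.
- **ORF coverage** — ORF nt length / sequence length.
- **Fickett TESTCODE** — the published position-asymmetry and composition
  lookup tables and weights; N bases are excluded from the counts.
- **Hexamer usage bias** — mean natural-log ratio of in-frame hexamer
  frequencies between the coding and noncoding training tables. Coding
  tables count step-3 (in-frame) hexamers of CDS read from position 0;
  noncoding tables count step-1 sliding hexamers; both use add-one
  pseudocounts, so all 4,096 ratios are finite. Hexamers containing N are
  skipped; an ORF with no scorable hexamer scores 0.

A logistic regression (scikit-learn, L2 default) over the four features is
fitted on a stratified training split; the decision cutoff is chosen on the
held-out fraction (default 25%) as the probability maximizing
sensitivity + specificity, evaluated at midpoints between adjacent held-out
probabilities so it lies strictly inside (0, 1). The historical bovine
cutoff 0.348 can be supplied as a fixed `cpat_cutoff`, but it is specific to
the training corpus it came from; synthetic or new-species runs should
derive their own ("train", the default).

The four noncoding rules are a pure conjunction, so their evaluation order
is irrelevant: probability < cutoff; conservation score strictly negative
when a score table is supplied (a score of exactly 0 fails); no recorded
domain hit when a hit table is supplied; maximal ORF ≤ 100 aa (the bound is
applied to the amino-acid length excluding the stop — ORF finders differ on
this convention, so it is fixed here). Absent optional tables pass
vacuously and the run report flags those filters as skipped. Conservation
and domain evidence enter only as precomputed tables; phylogenetic codon
modelling and profile-HMM search are out of scope. Three-frame peptide
translation is provided for exporting sequences to an external domain
scanner.

## Tissue specificity

The score of an expression vector is 1 − √JS(p, ê_t) maximized over
conditions t, with p the normalized vector, ê_t the single-condition
extremal pattern, and JS the Jensen–Shannon divergence with Shannon entropy
in bits (0·log 0 = 0). Entropy is computed directly rather than through a
normalizing wrapper so the extremes are exact: the score is exactly 1 iff
expression is confined to one condition, and uniform expression over n
conditions is the minimum over full-support vectors. Scores are invariant
to positive rescaling (so FPKM scale factors are irrelevant), maximization
over all conditions follows the "maximal JS" reading, ties go to the first
condition in declared order, and a score of exactly 0.5 is called
non-specific (the specific set requires a score strictly larger than the
cutoff). All-zero rows are reported as unscorable rather than silently
dropped. No expression floor is applied by default; near-zero noise vectors
can score spuriously high, which is why the planted-ubiquitous synthetic
profiles stay bounded away from zero.

## Catalogue comparison

Comparisons are at the transcript-locus (span) level, strand-blind, with a
1 bp minimum overlap — external catalogues vary in strand reliability and
exon annotation quality; both parameters are configurable. Membership of
each primary locus in every other catalogue gives Venn-style region counts
that partition the primary set.

## Cis-neighbor prediction and GO enrichment

A protein-coding gene (span = union of its transcripts' spans) is a
neighbor of a tissue-specific lincRNA if the edge-to-edge distance is at
most the window (default 50 kb, inclusive; overlap = distance 0; both
strands eligible). Pairs are scored by Pearson correlation across the
shared ordered condition set — Pearson is the normative choice, and pairs
with a zero-variance profile are dropped with a logged reason since their
correlation is undefined. "Strong" means |r| ≥ 0.9 by default; the
threshold is configurable and echoed in output metadata. Enrichment of the
strong-neighbor genes uses the hypergeometric upper tail P(X ≥ k) per term,
with BH correction within each GO category at FDR 0.05. The background is
all protein-coding genes with expression data (not all annotated genes);
GO DAG propagation is not performed.

## Final loci

Final lincRNAs are grouped into loci by single-linkage over same-strand
span overlap; each connected component is one putative noncoding gene.
Assemblers inherit their own undocumented locus merging, so the rule is
stated explicitly here and may differ from theirs.

## Synthetic data

The generator plants every structure the pipeline is supposed to recover,
at desk scale by default: 2 chromosomes × 2 Mb, 50 multi-exon coding genes
(3–7 exons of 150–300 bp, introns 300–1,500 bp) and 10 small-RNA genes on
evenly spaced anchors, ~200 assembled transcripts constructed by explicit
geometry to realize each class code, 10 conditions, and 500 + 500 training
sequences — a few seconds on one CPU. Intergenic (`u`) transcripts are
placed in deserts ≥ ~20 kb from every reference (far beyond the run-on
distance) yet within 50 kb of a flanking gene so neighbor analysis has
candidates.

Sequence regimes: noncoding sequences follow an AT-rich first-order Markov
background (25% self-transition bias) and are rejection-sampled to a
maximal ORF ≤ 100 aa; coding-labelled sequences embed an in-frame ORF of
101–299 aa (306–900 nt) whose codons draw from a GC-rich composition,
flanked by background UTRs, with each transcript's sequence length equal to
its spliced exon length. Training sets mirror the regimes (pure in-frame
CDS vs capped background). Expression planting: single-condition
transcripts are positive in exactly one condition; ubiquitous transcripts
draw U(5, 10) everywhere (bounded away from zero so they stay below the 0.5
cutoff at ≥ 5 conditions); correlated lincRNA–gene pairs share a latent
positive factor with one condition boosted ×50 (keeping the lincRNA
tissue-specific) plus half-normal noise of configurable sd — sd 0 gives
correlation exactly 1. The GO map assigns each of 20 terms at a 5% base
rate, with one planted term assigned to the correlated-neighbor genes at a
configurable fold (10× by default; 1× is the type-I null).

What the generator does **not** emulate: read-level noise, assembly
artifacts (fragmented or chimeric transfrags), realistic genome composition
and repeat content, isoform complexity within loci, FPKM estimation error,
or correlated GO annotation structure. Passing closed-loop tests therefore
demonstrates correctness of the algorithms under their stated definitions,
not performance on real tissue data, where class boundaries and coding
signals are far noisier.

## Numerical and reproducibility choices

- One `numpy` Generator seeded from the config drives every random choice;
  identical seeds give byte-identical output files (manifest paths are
  stored relative for this reason).
- Hexamer pseudocount 1; log base e for the hexamer score; Fickett lookup
  thresholds as published.
- Hypergeometric tails via `scipy.stats.hypergeom.sf`; BH via
  `statsmodels`; probabilities clamped to (0, 1].
- Degenerate inputs fail loudly: all-zero expression rows, zero-variance
  correlation profiles, single-class training sets, empty foregrounds,
  ragged or negative expression tables.
- Test problem sizes (e.g. 220-transcript class-code loops, 500-sequence
  ORF oracles, 200-replicate enrichment simulations) were chosen so the
  whole suite runs in seconds while keeping Monte-Carlo margins wide.

## Known limitations

- Class-code semantics approximate the Cuffcompare vocabulary from its
  documented definitions; undocumented corner cases (e.g. its exact
  junction-sharing rule for `j`, the `e` intron-intrusion measurement) are
  resolved explicitly as described above and may differ from the original
  tool on pathological inputs.
- The coding-potential model is trained per run; coefficients and cutoff
  are only as transferable as the training corpora.
- Locus grouping, enrichment background and the strong-correlation
  threshold are explicit conventions of this package; alternatives are
  configurable but change headline counts.
- GFF3, BAM/SAM and compressed inputs are not handled.
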