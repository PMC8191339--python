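# Methods

## Coordinates and domain model

All coordinates are 0-based half-open internally. GTF and STAR `SJ.out.tab`
are 1-based inclusive on disk and converted at the I/O boundary; BED is
native half-open. A transcript model is an ordered exon chain on one
chromosome/strand; its splice-junction chain (the ordered introns) is the
key object for classification. A splice junction decomposes into a donor
and an acceptor site in transcript sense: on the minus strand the donor is
the higher coordinate. Chromosome-name dialects ("chr1" vs "1") are not
normalized; a model on a chromosome absent from the genome raises.

## Isoform classification

Multi-exon isoforms go through a fixed cascade:

1. **FSM** — some same-strand reference transcript has an identical
   junction chain. When several transcripts share the chain, the match is
   the transcript minimizing the summed end distances d5+d3 (ties by
   transcript id), so outputs are reproducible.
2. **ISM** — the chain is a *consecutive, proper* sub-chain of a reference
   transcript's chain. An identical chain is FSM only.
3. **intergenic** — the genomic span overlaps no annotated gene span on
   either strand.
4. **genic_other** — span overlap exists only on the opposite strand and no
   splice site is shared. This category absorbs antisense/genic/fusion-like
   cases without finer subdivision.
5. **NIC** if every splice site (position *and* donor/acceptor side) is in
   the same-chromosome, same-strand annotated site set; **NNC** otherwise,
   with the unannotated sites reported.

The NIC site lookup uses all same-strand annotated sites on the chromosome,
not only the assigned gene's, because the category is defined by "annotated
splice sites" generally. Mono-exon isoforms cannot be chain-compared and get
their own labels (`mono_exon_known` when fully contained in an annotated
exon, `mono_exon_genic` when overlapping a locus, else intergenic); they are
reported separately and never merged into FSM/ISM/NIC/NNC.

Gene assignment maximizes shared same-strand splice sites, breaking ties by
exonic-overlap bases and then lexicographic gene id. End distances are
strand-aware absolute offsets (the 5′ end of a minus-strand model is its
genomic right end); "distant ends" are counted with a strict > 500 nt rule
against the minimum over all transcripts of the assigned gene.

The minority filter retains an isoform iff its total reads are ≥
`min_fraction` (default 1%) of its gene's total; exactly 1% is retained
("less than 1%" discards strictly below). Intergenic loci are single-linkage
clusters of genomic span overlap, strand-agnostic; touching-but-not-
overlapping spans stay separate (half-open semantics).

## CDS containment

Annotated peptides are built per gene by splicing CDS segments in
transcript order, applying the GTF frame offset of the first segment,
translating with the standard genetic code, stripping a terminal stop, and
deduplicating within the gene. A CDS whose length is not a multiple of
three is translated up to the last complete codon (logged). An isoform
"contains a full CDS" when one of its gene's peptides is a substring of one
of the three sense-strand frame translations of its spliced,
strand-corrected sequence. Stop codons are rendered `*` and translation
continues through them — the search is over whole frames, not ORFs — and
only the three sense frames are searched, since strand is handled upstream.
Peptides shorter than 2 aa are ignored as degenerate. Containment rates are
reported over multi-exon isoforms of coding genes only; selenoproteins and
non-standard codes are out of scope.

## Novel exons

A novel exon is an exon of an NNC isoform that overlaps *no* annotated exon
at all, on either strand (a 1-base overlap disqualifies). Exons are
deduplicated by exact coordinates; every occurrence is kept as a source with
its own strand-aware position class (first/middle/last in transcript order)
and junction requirement (one flanking junction for terminal exons, two for
internal ones). A deduplicated exon occurring at different positions in
different isoforms is counted under its first-encountered class, with all
per-source classes retained. The uniform-placement expectation for terminal
novel exons is `n_novel × n_isoforms / total_exons` (each isoform has
exactly one first and one last exon; the expectation is symmetric).
Validation against a short-read junction set succeeds when, for at least
one source isoform, every required junction is present; membership ignores
strand by default because typical short-read libraries are nondirectional
(strand-aware matching is a switch).

## Differential isoform usage

Counts are summed per condition (replicate collapse is the default; a
switch keeps per-sample columns for display-style analyses, and samples
excluded by the sample map's include flag — e.g. pilot runs — never enter).
The test is applied to the raw per-condition *counts*, not the percentage
table: a contingency test is only defined on counts; relative usage
(percent, columns summing to 100) is derived for display and effect
summaries. Genes need ≥50 reads in ≥2 conditions (both inclusive) to be
tested. All-zero rows/columns are dropped before computing
df = (r−1)(c−1); no Yates correction and no minimum-expected-count rule is
applied — the read filter is the only hard guard — but a deduplicated
warning is emitted when any expected count falls below 5. Bonferroni uses
m = number of genes actually tested. The effect summary is the maximum over
isoforms of the *population* standard deviation (ddof 0) of relative usage
across conditions with nonzero totals. Results are ranked by p-value, then
max usage SD descending, then gene id.

## Synthetic data

The generator defines the study conditions all recovery tests run under.

**Reference.** Genes are placed without overlap on both strands of random
chromosomes (default 2 × 400 kb, 30 genes, 3–8 exons of 80–300 nt, introns
250–1500 nt, ≥3 kb spacing). Every gene's master transcript carries a CDS
that begins ATG, ends in a stop, contains no internal stops, and occupies
an interior range of the spliced sequence — each UTR takes up to ~40% of
the transcript, so UTRs frequently span whole terminal exons, as in real
annotations. Alternate transcripts are consecutive exon windows of the
master. The genome is random sequence with the CDS codons written in
(strand-corrected).

**Observed isoforms** (default mix 40% FSM, 15% ISM, 20% NIC, 15% NNC, 10%
intergenic) are built per category and *certified* against definitional
checks (chain identity, consecutive sub-chain, site membership, locus
overlap) with resampling, so the emitted truth labels are guaranteed:

- FSM: copies with transcript-end jitter. Offsets are exponential
  (scale 50 nt) in a random direction — real end offsets concentrate near
  annotated ends — with an 8% tail of outward extensions beyond 520 nt to
  exercise the distant-end analysis.
- ISM: consecutive proper sub-chains of ≥3-exon transcripts.
- NIC: exon skips. 55% of events skip an exon wholly outside the CDS
  (alternative UTR structure — the dominant real NIC mode, which is why
  real NIC isoforms usually retain the CDS), the rest skip a uniformly
  random internal exon.
- NNC: splice-site shifts of ±5–50 nt, or novel exons (60–120 nt) injected
  into intron interiors with ≥50 nt clearance. Injected exons are recorded
  in the truth manifest; they are internal by construction, so terminal
  novel-exon classes are exercised by unit tests with hand-built models
  rather than by the generator.
- intergenic: 2–4-exon models placed in annotation gaps with ≥300 nt
  margins. The generator emits multi-exon intergenic models only (the
  locus-grouping analysis concerns multi-exon isoforms); mono-exon
  categories are covered by unit tests.

**Counts.** Five conditions × two replicates by default. Per gene, a null
usage vector is drawn from a symmetric Dirichlet (concentration 2 — a
realistically uneven usage profile); a `switch_fraction` of multi-isoform
genes instead get condition-group-specific vectors in which the two largest
isoforms' combined mass is split 80/20 in the first half of conditions and
20/80 in the second. Reads per gene per condition are lognormal across
genes (median 200, σ=1) with Poisson sampling per condition, or fixed for
calibration runs; counts are multinomial per replicate. The RPM table
mimics an independent short-read assay: it covers annotated genes
(including those without observed isoforms, which receive Poisson
background reads at their own lognormal mean) and excludes unannotated
intergenic loci. At desk scale (tens of genes) RPM magnitudes are large, so
most genes land in the top expression bin; the binned detection and
isoform-count properties are additionally exercised in tests with
purpose-built tables.

**Junctions.** One row per distinct junction of the observed models,
dropped independently with the configured probability (default 5%), support
counts Poisson(20)+1, written in `SJ.out.tab` convention.

One seed governs everything; per-stage sub-seeds are spawned
deterministically so stages can be re-run independently, and outputs are
byte-identical under a fixed seed. Counts are generated at isoform level
directly; read-level artifacts (sequencing error, consensus accuracy,
multi-mapping) are upstream of this package and not modeled — so passing
recovery tests demonstrate correctness of the downstream definitions and
statistics, not robustness to alignment or isoform-calling noise.

## Calibration

`scripts/acceptance.py` estimates the familywise error rate of the DIU
procedure under a global null: 500 replicate datasets of 200 genes × 4
conditions, 3 isoforms per gene, usage Dirichlet(2,2,2) shared across
conditions, multinomial counts at 100 reads per condition; the reported
value is the fraction of datasets with ≥1 Bonferroni-significant gene at
α = 0.05, which the correction should keep at or below 0.05.

## Numerical and degenerate-input choices

- Zero-length or overlapping exons in inputs are rejected with diagnostics
  (GTF records logged and skipped; constructed models raise).
- A condition column with zero total reads has undefined (NaN) usage and is
  excluded from testing and SD computation; a gene with <2 usable rows or
  columns is "untestable" and excluded from the Bonferroni m.
- Expression bins are lower-exclusive/upper-inclusive
  ((0.05,3], (3,5], (5,10], (10,20], (20,∞)); empty bins report NaN, not 0.
  The expressed-gene rule is strictly > 0.05 mean RPM.
- Records with zero total reads are kept but flagged.
- Codons containing N translate to X; incomplete trailing codons are
  dropped per frame.

## Known limitations

- SQANTI-style attributes beyond the category (RT-switching, coverage,
  polyA motifs) are not implemented; `genic_other` is deliberately coarse.
- No read-level simulation, no BAM/FASTQ handling; isoform models and
  counts are inputs.
- Gene-level differential expression is out of scope (usage ≠ expression).
- The generator does not emit fusion or antisense isoforms; `genic_other`
  is exercised by hand-built cases only.
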