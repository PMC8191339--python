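"""SQANTI-style isoform categorization against a reference annotation.

A multi-exon isoform is compared to the annotation by its splice-junction
chain: FSM (chain identical to an annotated transcript), ISM (consecutive
proper sub-chain of one), NIC (all splice sites annotated but the chain is
novel), NNC (at least one unannotated splice site), intergenic (span overlaps
no annotated locus) or genic_other (overlap only on the opposite strand with
no shared sites). Mono-exon isoforms get their own categories since they have
no junction chain to compare.
"""

from __future__ import annotations

import enum
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotation import Gene, GenomeAnnotation, IsoformRecord
from .intervals import GenomicInterval, SpliceSite, TranscriptModel

log = logging.getLogger(__name__)


class Category(str, enum.Enum):
    FSM = "FSM"
    ISM = "ISM"
    NIC = "NIC"
    NNC = "NNC"
    MONO_EXON_KNOWN = "mono_exon_known"
    MONO_EXON_GENIC = "mono_exon_genic"
    GENIC_OTHER = "genic_other"
    INTERGENIC = "intergenic"


@dataclass
class IsoformClassification:
    isoform_id: str
    category: Category
    assigned_gene: str | None = None
    matched_transcript: str | None = None
    novel_sites: tuple[SpliceSite, ...] = ()
    d5: int | None = None  # |5' end - matched transcript TSS|, FSM only
    d3: int | None = None  # |3' end - matched transcript polyA|, FSM only
    d5_gene_min: int | None = None
    d3_gene_min: int | None = None

    def __post_init__(self) -> None:
        if (self.matched_transcript is not None) != (self.category in (Category.FSM, Category.ISM)):
            raise ValueError(
                f"{self.isoform_id}: matched_transcript must be set iff category is FSM/ISM"
            )
        if (len(self.novel_sites) > 0) != (self.category is Category.NNC):
            raise ValueError(f"{self.isoform_id}: novel_sites must be non-empty iff NNC")


@dataclass
class IntergenicLocus:
    locus_id: str
    members: list[str]
    span: GenomicInterval


# ------------------------------------------------------------------ helpers


def _is_consecutive_subchain(model: TranscriptModel, annotation: GenomeAnnotation) -> str | None:
    """Transcript id whose chain contains the model's chain as a consecutive
    proper sub-chain, or None. Candidates are found via the first junction."""
    chain = model.chain_key
    for tid, pos in annotation.transcripts_containing_junction(model.junction_chain[0]):
        ref = annotation.transcripts[tid].chain_key
        if len(ref) > len(chain) and ref[pos : pos + len(chain)] == chain:
            return tid
    return None


def _end_distances_to(model: TranscriptModel, ref: TranscriptModel) -> tuple[int, int]:
    return abs(model.five_prime - ref.five_prime), abs(model.three_prime - ref.three_prime)


def assign_gene(model: TranscriptModel, annotation: GenomeAnnotation) -> str | None:
    """Gene whose transcripts share the most splice sites with the model;
    ties broken by exonic-overlap bases, then lexicographic gene_id."""
    candidates = annotation.genes_overlapping(model.span)
    if not candidates:
        return None
    model_sites = {(s.position, s.side) for s in model.splice_sites()}

    def score(gene: Gene) -> tuple[int, int, str]:
        shared = 0
        if gene.strand == model.strand and model_sites:
            gene_sites: set[tuple[int, str]] = set()
            for t in gene.transcripts:
                gene_sites.update((s.position, s.side) for s in t.splice_sites())
            shared = len(model_sites & gene_sites)
        overlap = 0
        for t in gene.transcripts:
            for ge in t.exons:
                for me in model.exons:
                    overlap += me.overlap_length(ge)
        return (shared, overlap, gene.gene_id)

    def sort_key(gene: Gene) -> tuple[int, int, str]:
        shared, overlap, gid = score(gene)
        return (-shared, -overlap, gid)

    return min(candidates, key=sort_key).gene_id


def end_distances(
    classification: IsoformClassification,
    model: TranscriptModel,
    annotation: GenomeAnnotation,
) -> tuple[int, int, int, int]:
    """(d5_matched, d3_matched, d5_gene_min, d3_gene_min) for an FSM isoform.

    Distances are strand-aware absolute nucleotide offsets between the
    model's 5'/3' ends and the matched transcript's TSS/polyA site; the
    gene-min variants minimize over all transcripts of the assigned gene.
    """
    if classification.category is not Category.FSM:
        raise ValueError("end_distances is defined for FSM isoforms only")
    matched = annotation.transcripts[classification.matched_transcript]
    d5, d3 = _end_distances_to(model, matched)
    gene = annotation.genes[classification.assigned_gene]
    d5_min = min(abs(model.five_prime - t.five_prime) for t in gene.transcripts)
    d3_min = min(abs(model.three_prime - t.three_prime) for t in gene.transcripts)
    return d5, d3, d5_min, d3_min


# ------------------------------------------------------------------ classifier


def classify_isoform(model: TranscriptModel, annotation: GenomeAnnotation) -> IsoformClassification:
    """Assign one isoform its category (decision cascade, see module docstring)."""
    if model.n_exons == 1:
        return _classify_mono_exon(model, annotation)

    # (1) FSM: identical chain; among chain-identical transcripts pick the
    # one with the closest ends (min d5+d3, ties by transcript id).
    fsm_candidates = annotation.transcripts_with_chain(model)
    if fsm_candidates:
        matched = min(
            fsm_candidates,
            key=lambda tid: (sum(_end_distances_to(model, annotation.transcripts[tid])), tid),
        )
        gene = assign_gene(model, annotation) or annotation.gene_of_transcript[matched]
        cls = IsoformClassification(
            model.id, Category.FSM, assigned_gene=gene, matched_transcript=matched
        )
        cls.d5, cls.d3, cls.d5_gene_min, cls.d3_gene_min = end_distances(cls, model, annotation)
        return cls

    # (2) ISM: consecutive proper sub-chain.
    ism_match = _is_consecutive_subchain(model, annotation)
    if ism_match is not None:
        gene = assign_gene(model, annotation) or annotation.gene_of_transcript[ism_match]
        return IsoformClassification(
            model.id, Category.ISM, assigned_gene=gene, matched_transcript=ism_match
        )

    # (3) intergenic: span overlaps no annotated locus on either strand.
    overlapping = annotation.genes_overlapping(model.span)
    if not overlapping:
        return IsoformClassification(model.id, Category.INTERGENIC)

    # (5) opposite-strand-only overlap with no shared sites -> genic_other.
    novel = tuple(annotation.unannotated_sites(model))
    same_strand_overlap = any(g.strand == model.strand for g in overlapping)
    n_sites = len(model.splice_sites())
    shares_sites = len(novel) < n_sites
    if not same_strand_overlap and not shares_sites:
        return IsoformClassification(model.id, Category.GENIC_OTHER)

    # (4) NIC if every splice site is annotated (same chrom/strand), else NNC.
    gene = assign_gene(model, annotation)
    if not novel:
        return IsoformClassification(model.id, Category.NIC, assigned_gene=gene)
    return IsoformClassification(model.id, Category.NNC, assigned_gene=gene, novel_sites=novel)


def _classify_mono_exon(model: TranscriptModel, annotation: GenomeAnnotation) -> IsoformClassification:
    exon = model.exons[0]
    hits = annotation.exons_overlapping(exon)
    if any(h.interval.contains(exon) for h in hits):
        return IsoformClassification(
            model.id, Category.MONO_EXON_KNOWN, assigned_gene=assign_gene(model, annotation)
        )
    if annotation.genes_overlapping(model.span):
        return IsoformClassification(
            model.id, Category.MONO_EXON_GENIC, assigned_gene=assign_gene(model, annotation)
        )
    return IsoformClassification(model.id, Category.INTERGENIC)


def classify_all(
    records: Iterable[IsoformRecord] | Iterable[TranscriptModel],
    annotation: GenomeAnnotation,
) -> dict[str, IsoformClassification]:
    out = {}
    for rec in records:
        model = rec.model if isinstance(rec, IsoformRecord) else rec
        out[model.id] = classify_isoform(model, annotation)
    return out


# ------------------------------------------------------------------ summaries


def count_distant_ends(
    classifications: Iterable[IsoformClassification], threshold: int = 500
) -> tuple[int, int]:
    """FSM isoforms whose 5'/3' end is more than ``threshold`` nt away from
    any annotated TSS / polyA site of their gene (strict inequality)."""
    n5 = n3 = 0
    for c in classifications:
        if c.category is not Category.FSM:
            continue
        if c.d5_gene_min is not None and c.d5_gene_min > threshold:
            n5 += 1
        if c.d3_gene_min is not None and c.d3_gene_min > threshold:
            n3 += 1
    return n5, n3


def filter_minority_isoforms(
    records: Sequence[IsoformRecord],
    gene_of: Mapping[str, str | None],
    min_fraction: float = 0.01,
) -> list[IsoformRecord]:
    """Drop isoforms carrying less than ``min_fraction`` of their gene's reads.

    An isoform with exactly the threshold fraction is retained ("less than"
    discards strictly below). Genes with zero total reads keep all isoforms.
    """
    totals: dict[str | None, int] = defaultdict(int)
    for rec in records:
        totals[gene_of.get(rec.id)] += rec.total
    kept = []
    for rec in records:
        gene = gene_of.get(rec.id)
        gene_total = totals[gene]
        if gene_total == 0:
            log.info("gene %s has zero reads; all isoforms retained", gene)
            kept.append(rec)
        elif rec.total >= min_fraction * gene_total:
            kept.append(rec)
    return kept


def cluster_intergenic_loci(
    models: Sequence[TranscriptModel],
    multiexon_only: bool = True,
) -> list[IntergenicLocus]:
    """Single-linkage clustering of intergenic isoforms by genomic span
    overlap (strand-agnostic). Touching-but-not-overlapping spans are
    separate loci."""
    pool = [m for m in models if not multiexon_only or m.n_exons > 1]
    by_chrom: dict[str, list[TranscriptModel]] = defaultdict(list)
    for m in pool:
        by_chrom[m.chrom].append(m)
    loci: list[IntergenicLocus] = []
    for chrom in sorted(by_chrom):
        ms = sorted(by_chrom[chrom], key=lambda m: (m.span.start, m.span.end, m.id))
        current: list[TranscriptModel] = []
        cur_end = -1
        for m in ms:
            if current and m.span.start < cur_end:
                current.append(m)
                cur_end = max(cur_end, m.span.end)
            else:
                if current:
                    loci.append(_make_locus(current, len(loci)))
                current = [m]
                cur_end = m.span.end
        if current:
            loci.append(_make_locus(current, len(loci)))
    return loci


def _make_locus(members: list[TranscriptModel], index: int) -> IntergenicLocus:
    start = min(m.span.start for m in members)
    end = max(m.span.end for m in members)
    return IntergenicLocus(
        locus_id=f"locus_{index + 1}",
        members=[m.id for m in members],
        span=GenomicInterval(members[0].chrom, start, end),
    )
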