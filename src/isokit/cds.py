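"""Coding-potential analysis: does an isoform contain a full annotated CDS?

The check is peptide-level: each isoform's spliced, strand-corrected sequence
is translated in all three reading frames (stop codons rendered as ``*``,
translation continuing through them) and an isoform "contains a full CDS"
when one of its gene's annotated peptides occurs as a substring of one of
those frame translations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.Seq import Seq

from .annotation import GenomeAnnotation
from .classify import Category, IsoformClassification
from .intervals import TranscriptModel
from .io import spliced_sequence

log = logging.getLogger(__name__)

#: Peptides shorter than this many residues are ignored as degenerate
#: (an "M"-only peptide would match almost any transcript).
MIN_PEPTIDE_LENGTH = 2


@dataclass
class CdsContainmentResult:
    isoform_id: str
    gene_id: str | None
    multiexon: bool
    applicable: bool  # False when the assigned gene has no annotated CDS
    contains_full_cds: bool = False
    matched_peptide_id: str | None = None
    frame: int | None = None

    def __post_init__(self) -> None:
        if self.contains_full_cds and (self.matched_peptide_id is None or self.frame is None):
            raise ValueError(f"{self.isoform_id}: positive result must carry peptide id and frame")


def translate_three_frames(seq: str) -> tuple[str, str, str]:
    """Translate the three sense-strand frames of a (strand-corrected)
    transcript sequence. Incomplete trailing codons are dropped; stops are
    ``*``; codons containing N become ``X``."""
    out = []
    for offset in range(3):
        sub = seq[offset:]
        sub = sub[: len(sub) - len(sub) % 3]
        out.append(str(Seq(sub).translate()) if sub else "")
    return tuple(out)  # type: ignore[return-value]


def _transcript_order_cds(model: TranscriptModel) -> list:
    segs = sorted(model.cds, key=lambda s: s.interval.start)
    return segs if model.strand == "+" else segs[::-1]


def reference_peptides(
    annotation: GenomeAnnotation, genome: Mapping[str, object]
) -> dict[str, dict[str, str]]:
    """Per gene, annotated protein sequences keyed by a stable peptide id.

    CDS segments are spliced in transcript order, the GTF frame offset of the
    first segment is applied, the standard genetic code translates the result
    and a terminal stop is removed. Identical peptides are deduplicated
    within a gene. A CDS whose length is not a multiple of three after the
    frame adjustment is translated up to the last complete codon (logged).
    """
    peptides: dict[str, dict[str, str]] = {}
    for gid in sorted(annotation.genes):
        gene = annotation.genes[gid]
        seen: dict[str, str] = {}
        for t in sorted(gene.transcripts, key=lambda t: t.id):
            if not t.cds:
                continue
            cds_model = TranscriptModel(
                id=t.id, chrom=t.chrom, strand=t.strand,
                exons=tuple(seg.interval for seg in t.cds),
            )
            nt = spliced_sequence(cds_model, genome)
            frame = _transcript_order_cds(t)[0].frame
            nt = nt[frame:]
            if len(nt) % 3:
                log.warning("transcript %s: CDS length not divisible by 3; truncating", t.id)
                nt = nt[: len(nt) - len(nt) % 3]
            pep = str(Seq(nt).translate())
            if pep.endswith("*"):
                pep = pep[:-1]
            if pep and pep not in seen.values():
                seen[f"{gid}_cds{len(seen) + 1}"] = pep
        if seen:
            peptides[gid] = seen
    return peptides


def contains_full_cds(
    model: TranscriptModel,
    classification: IsoformClassification,
    annotation: GenomeAnnotation,
    genome: Mapping[str, object],
    peptides: dict[str, dict[str, str]] | None = None,
    min_peptide_length: int = MIN_PEPTIDE_LENGTH,
) -> CdsContainmentResult:
    """Check whether the isoform contains a full annotated CDS of its gene."""
    if peptides is None:
        peptides = reference_peptides(annotation, genome)
    gene = classification.assigned_gene
    gene_peps = peptides.get(gene, {}) if gene else {}
    result = CdsContainmentResult(
        isoform_id=model.id,
        gene_id=gene,
        multiexon=model.n_exons > 1,
        applicable=bool(gene_peps),
    )
    if not gene_peps:
        return result
    frames = translate_three_frames(spliced_sequence(model, genome))
    for pep_id in sorted(gene_peps):
        pep = gene_peps[pep_id]
        if len(pep) < min_peptide_length:
            continue
        for frame, translation in enumerate(frames):
            if pep in translation:
                result.contains_full_cds = True
                result.matched_peptide_id = pep_id
                result.frame = frame
                return result
    return result


def containment_rates(
    results: Iterable[CdsContainmentResult],
    classifications: Mapping[str, IsoformClassification],
) -> dict[str, float]:
    """Per category, the fraction of multi-exon isoforms of coding genes that
    contain a full CDS. Mono-exon and not-applicable isoforms are excluded
    from the denominators."""
    num: dict[str, int] = {}
    den: dict[str, int] = {}
    for r in results:
        if not r.multiexon or not r.applicable:
            continue
        cat = classifications[r.isoform_id].category.value
        den[cat] = den.get(cat, 0) + 1
        if r.contains_full_cds:
            num[cat] = num.get(cat, 0) + 1
    return {cat: num.get(cat, 0) / den[cat] for cat in den}
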