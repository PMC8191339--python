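"""Discovery and short-read validation of unannotated exons in NNC isoforms.

A novel exon is an exon of an NNC isoform whose genomic location overlaps no
annotated exon at all, on either strand. Terminal novel exons require one
supporting splice junction in short-read data, internal ones two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotation import GenomeAnnotation, IsoformRecord, JunctionSet
from .classify import Category, IsoformClassification
from .intervals import GenomicInterval, SpliceJunction, TranscriptModel

FIRST, MIDDLE, LAST = "first", "middle", "last"


@dataclass
class NovelExonSource:
    """One occurrence of a novel exon inside a source isoform."""

    isoform_id: str
    transcript_exon_index: int  # position in transcript (5'->3') order
    position_class: str  # first | middle | last
    required_junctions: tuple[SpliceJunction, ...]


@dataclass
class NovelExon:
    interval: GenomicInterval
    sources: list[NovelExonSource] = field(default_factory=list)
    validated: bool | None = None
    supporting_counts: dict[tuple[str, int, int], int] = field(default_factory=dict)

    @property
    def position_class(self) -> str:
        """Position class of the first-encountered source (used for counting);
        per-source classes remain available on :attr:`sources`."""
        return self.sources[0].position_class


def position_class(model: TranscriptModel, genomic_exon_index: int) -> str:
    """first/middle/last in transcript order; on '-' the genomically last
    exon is transcript-first. Mono-exon models are a contract violation."""
    if model.n_exons == 1:
        raise ValueError("position_class undefined for mono-exon models")
    t_idx = model.exon_transcript_index(genomic_exon_index)
    if t_idx == 0:
        return FIRST
    if t_idx == model.n_exons - 1:
        return LAST
    return MIDDLE


def _adjacent_junctions(model: TranscriptModel, genomic_exon_index: int) -> tuple[SpliceJunction, ...]:
    """The junction(s) flanking an exon: one for terminal exons, two for
    internal ones."""
    chain = model.junction_chain
    out = []
    if genomic_exon_index > 0:
        out.append(chain[genomic_exon_index - 1])
    if genomic_exon_index < model.n_exons - 1:
        out.append(chain[genomic_exon_index])
    return tuple(out)


def find_novel_exons(
    nnc_records: Iterable[IsoformRecord] | Iterable[TranscriptModel],
    annotation: GenomeAnnotation,
    classifications: Mapping[str, IsoformClassification] | None = None,
) -> list[NovelExon]:
    """Exons of NNC isoforms with zero overlap against any annotated exon,
    deduplicated by exact (chrom, start, end); every occurrence is recorded
    as a source with its own position class and junction requirement."""
    found: dict[tuple[str, int, int], NovelExon] = {}
    for rec in nnc_records:
        model = rec.model if isinstance(rec, IsoformRecord) else rec
        if classifications is not None:
            cls = classifications.get(model.id)
            if cls is None or cls.category is not Category.NNC:
                continue
        for g_idx, exon in enumerate(model.exons):
            if annotation.exons_overlapping(exon):
                continue
            key = (exon.chrom, exon.start, exon.end)
            ne = found.setdefault(key, NovelExon(GenomicInterval(exon.chrom, exon.start, exon.end)))
            ne.sources.append(
                NovelExonSource(
                    isoform_id=model.id,
                    transcript_exon_index=model.exon_transcript_index(g_idx),
                    position_class=position_class(model, g_idx),
                    required_junctions=_adjacent_junctions(model, g_idx),
                )
            )
    return [found[k] for k in sorted(found)]


def expected_terminal_novel_exons(
    all_records: Sequence[IsoformRecord] | Sequence[TranscriptModel],
    n_novel: int,
) -> tuple[float, float]:
    """Expected numbers of novel first and last exons under uniform placement
    of ``n_novel`` exons across all exons of all isoforms: each isoform
    contributes exactly one first and one last exon, so the expectation is
    ``n_novel * n_isoforms / total_exons`` for each (symmetric)."""
    if n_novel < 0:
        raise ValueError("n_novel must be >= 0")
    models = [r.model if isinstance(r, IsoformRecord) else r for r in all_records]
    total_exons = sum(m.n_exons for m in models)
    if total_exons == 0:
        raise ValueError("no exons among records")
    expected = n_novel * len(models) / total_exons
    return expected, expected


def validate_with_junctions(
    novel_exons: Sequence[NovelExon],
    junctions: JunctionSet,
    strand_aware: bool = False,
) -> list[NovelExon]:
    """Mark each novel exon validated when, for at least one source isoform,
    every required flanking junction is present in the short-read set."""
    for ne in novel_exons:
        ne.validated = False
        for src in ne.sources:
            for j in src.required_junctions:
                ne.supporting_counts[j.coords] = junctions.count(j, strand_aware=strand_aware)
            if all(junctions.contains(j, strand_aware=strand_aware) for j in src.required_junctions):
                ne.validated = True
        # keep scanning sources above so supporting_counts is complete
    return list(novel_exons)


def validation_rate(novel_exons: Sequence[NovelExon]) -> float:
    if not novel_exons:
        return float("nan")
    return sum(1 for ne in novel_exons if ne.validated) / len(novel_exons)


def write_novel_exons_bed(novel_exons: Sequence[NovelExon], path) -> None:
    with open(path, "w") as fh:
        for i, ne in enumerate(novel_exons, start=1):
            iv = ne.interval
            flag = int(bool(ne.validated))
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tnovel_exon_{i}|{ne.position_class}\t{flag}\t.\n")
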