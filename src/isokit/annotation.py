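"""Indexed reference annotation and supporting containers.

`GenomeAnnotation` holds genes and transcripts with the overlap/junction
indexes the classifier needs; `IsoformRecord` couples an observed isoform
model to its per-sample read counts; `JunctionSet` holds short-read splice
junctions with support counts.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from intervaltree import IntervalTree

from .intervals import GenomicInterval, SpliceJunction, SpliceSite, TranscriptModel

log = logging.getLogger(__name__)


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)
    name: str | None = None
    biotype: str | None = None

    @property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def is_coding(self) -> bool:
        return any(t.cds for t in self.transcripts)


@dataclass(frozen=True)
class ExonHit:
    """One annotated exon returned by an overlap query."""

    gene_id: str
    transcript_id: str
    interval: GenomicInterval


class GenomeAnnotation:
    """A reference annotation indexed for classification queries.

    Provides exon/gene overlap queries, the per-(chrom, strand) annotated
    splice-site set, exact junction-chain lookup (for full-splice matches)
    and a junction->transcript index (for incomplete-splice matches).
    """

    def __init__(self, genes: Iterable[Gene]):
        self.genes: dict[str, Gene] = {}
        self.transcripts: dict[str, TranscriptModel] = {}
        self.gene_of_transcript: dict[str, str] = {}
        self._exon_tree: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._gene_tree: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.splice_site_set: dict[tuple[str, str], set[tuple[int, str]]] = defaultdict(set)
        self._chain_index: dict[tuple[str, str, tuple], list[str]] = defaultdict(list)
        self._junction_index: dict[tuple[str, str, int, int], list[tuple[str, int]]] = defaultdict(list)

        for gene in genes:
            if gene.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {gene.gene_id}")
            if not gene.transcripts:
                raise ValueError(f"gene {gene.gene_id} has no transcripts")
            self.genes[gene.gene_id] = gene
            for t in gene.transcripts:
                if t.id in self.transcripts:
                    raise ValueError(f"transcript {t.id} assigned to more than one gene")
                self.transcripts[t.id] = t
                self.gene_of_transcript[t.id] = gene.gene_id
                for e in t.exons:
                    self._exon_tree[t.chrom].addi(e.start, e.end, ExonHit(gene.gene_id, t.id, e))
                for site in t.splice_sites():
                    self.splice_site_set[(t.chrom, t.strand)].add((site.position, site.side))
                self._chain_index[(t.chrom, t.strand, t.chain_key)].append(t.id)
                for i, j in enumerate(t.junction_chain):
                    self._junction_index[(j.chrom, j.strand, j.intron_start, j.intron_end)].append((t.id, i))
            span = gene.span
            self._gene_tree[gene.chrom].addi(span.start, span.end, gene.gene_id)

    # ------------------------------------------------------------------ queries

    def exons_overlapping(self, interval: GenomicInterval, strand: str | None = None) -> list[ExonHit]:
        """All annotated exons intersecting ``interval`` (optionally strand-filtered)."""
        hits = [iv.data for iv in self._exon_tree[interval.chrom].overlap(interval.start, interval.end)]
        if strand is not None:
            hits = [h for h in hits if h.interval.strand == strand]
        return hits

    def genes_overlapping(self, interval: GenomicInterval) -> list[Gene]:
        """All genes whose span intersects ``interval`` (strand-agnostic)."""
        ids = {iv.data for iv in self._gene_tree[interval.chrom].overlap(interval.start, interval.end)}
        return [self.genes[g] for g in sorted(ids)]

    def transcripts_with_chain(self, model: TranscriptModel) -> list[str]:
        """Same-strand reference transcripts whose junction chain equals the model's."""
        return list(self._chain_index.get((model.chrom, model.strand, model.chain_key), ()))

    def transcripts_containing_junction(self, j: SpliceJunction) -> list[tuple[str, int]]:
        return list(self._junction_index.get((j.chrom, j.strand, j.intron_start, j.intron_end), ()))

    def has_site(self, site: SpliceSite) -> bool:
        return (site.position, site.side) in self.splice_site_set.get((site.chrom, site.strand), ())

    def unannotated_sites(self, model: TranscriptModel) -> list[SpliceSite]:
        return sorted(s for s in model.splice_sites() if not self.has_site(s))

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class IsoformRecord:
    """An observed isoform model with per-sample read counts."""

    model: TranscriptModel
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sample, c in self.counts.items():
            if c < 0:
                raise ValueError(f"isoform {self.model.id}: negative count for sample {sample}")

    @property
    def id(self) -> str:
        return self.model.id

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def zero_total(self) -> bool:
        return self.total == 0

    def condition_totals(self, sample_map: "SampleMap") -> dict[str, int]:
        out: dict[str, int] = {c: 0 for c in sample_map.conditions}
        for sample, c in self.counts.items():
            if sample_map.included(sample):
                out[sample_map.condition_of(sample)] += c
        return out


@dataclass(frozen=True)
class SampleInfo:
    sample: str
    condition: str
    replicate: str = "1"
    include: bool = True


class SampleMap:
    """Sample -> condition map with an include flag (e.g. to drop pilot runs)."""

    def __init__(self, samples: Iterable[SampleInfo]):
        self._by_sample: dict[str, SampleInfo] = {}
        for s in samples:
            if s.sample in self._by_sample:
                raise ValueError(f"duplicate sample {s.sample}")
            self._by_sample[s.sample] = s

    def __contains__(self, sample: str) -> bool:
        return sample in self._by_sample

    def __len__(self) -> int:
        return len(self._by_sample)

    def included(self, sample: str) -> bool:
        return self._by_sample[sample].include

    def condition_of(self, sample: str) -> str:
        return self._by_sample[sample].condition

    def replicate_of(self, sample: str) -> str:
        return self._by_sample[sample].replicate

    @property
    def samples(self) -> list[str]:
        return [s for s in self._by_sample]

    @property
    def included_samples(self) -> list[str]:
        return [s for s, info in self._by_sample.items() if info.include]

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for info in self._by_sample.values():
            if info.include and info.condition not in seen:
                seen.append(info.condition)
        return seen


class JunctionSet:
    """Splice junctions with supporting read counts (e.g. from short reads).

    Membership is exact-coordinate. By default lookup ignores strand, which is
    the right behaviour for nondirectional short-read libraries; pass
    ``strand_aware=True`` to require a strand match (entries recorded as
    unstranded then match any query strand).
    """

    def __init__(self) -> None:
        # (chrom, intron_start, intron_end) -> {strand: count}
        self._data: dict[tuple[str, int, int], dict[str, int]] = {}

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[SpliceJunction, int]]) -> "JunctionSet":
        js = cls()
        for j, count in pairs:
            js.add(j, count)
        return js

    def add(self, j: SpliceJunction, count: int = 1) -> None:
        strands = self._data.setdefault(j.coords, {})
        strands[j.strand] = strands.get(j.strand, 0) + count

    def contains(self, j: SpliceJunction, strand_aware: bool = False) -> bool:
        strands = self._data.get(j.coords)
        if strands is None:
            return False
        if not strand_aware:
            return True
        return j.strand in strands or "." in strands

    def count(self, j: SpliceJunction, strand_aware: bool = False) -> int:
        strands = self._data.get(j.coords)
        if strands is None:
            return 0
        if strand_aware:
            return strands.get(j.strand, 0) + strands.get(".", 0)
        return sum(strands.values())

    def __len__(self) -> int:
        return len(self._data)

    def __iter__(self) -> Iterator[SpliceJunction]:
        for (chrom, s, e), strands in self._data.items():
            for strand in strands:
                yield SpliceJunction(chrom, strand, s, e)
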