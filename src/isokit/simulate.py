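"""Synthetic genomes, annotations, isoforms, counts and junction files with
ground truth.

The generator emulates the inputs of the long-read isoform workflow: a
multi-isoform annotation on both strands with coding transcripts, observed
isoforms of every category (exact copies with transcript-end jitter,
truncations, annotated-site recombinations, site shifts and injected novel
exons, and intergenic models), per-condition read counts drawn from a
Dirichlet-multinomial with optional injected usage switches, a gene RPM
table, and a short-read junction file with controllable dropout. Every
stage is deterministic under a fixed seed and records its truth in a
serializable manifest.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import Gene, GenomeAnnotation, IsoformRecord, SampleInfo, SampleMap
from .diu import UsageTable
from .intervals import CdsSegment, GenomicInterval, SpliceJunction, TranscriptModel
from . import io as iio

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_STOPS = ("TAA", "TAG", "TGA")
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SENSE_CODONS = [c for c in _CODONS if c not in _STOPS]

DEFAULT_CONDITIONS = ("NoStim", "LPS", "PAM", "R848", "PolyIC")

FSM, ISM, NIC, NNC, INTERGENIC = "FSM", "ISM", "NIC", "NNC", "intergenic"


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults describe a small but realistic study
    with five stimulation conditions and two replicates."""

    seed: int = 42
    # reference
    n_chromosomes: int = 2
    chromosome_length: int = 400_000
    n_genes: int = 30
    transcripts_per_gene: tuple[int, int] = (1, 3)
    exons_per_transcript: tuple[int, int] = (3, 8)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (250, 1500)
    gene_spacing: int = 3000
    # observed isoforms; mix order: FSM, ISM, NIC, NNC, intergenic
    n_observed_isoforms: int = 150
    category_mix: tuple[float, float, float, float, float] = (0.4, 0.15, 0.2, 0.15, 0.1)
    end_jitter_scale: int = 50  # exponential scale of typical end offsets
    distant_end_fraction: float = 0.08  # FSM ends extended beyond the 500 nt cutoff
    end_jitter_max: int = 800
    nic_utr_fraction: float = 0.55  # NIC events that restructure UTR exons only
    novel_exon_fraction: float = 0.5  # of NNC isoforms carry an injected exon
    min_exon_length: int = 20
    # counts
    n_conditions: int = 5
    n_replicates: int = 2
    reads_per_gene_per_condition: int = 200
    reads_distribution: str = "lognormal"  # fixed | poisson | lognormal
    reads_lognormal_sigma: float = 1.0
    dirichlet_concentration: float = 2.0
    switch_fraction: float = 0.1
    switch_usage: tuple[float, float] = (0.8, 0.2)
    # junctions
    junction_dropout: float = 0.05

    def __post_init__(self) -> None:
        if abs(sum(self.category_mix) - 1.0) > 1e-9:
            raise ValueError("category_mix must sum to 1")
        if any(f < 0 for f in self.category_mix):
            raise ValueError("category_mix fractions must be in [0, 1]")
        if not 0.0 <= self.junction_dropout <= 1.0:
            raise ValueError("junction_dropout must be in [0, 1]")
        if not 0.0 <= self.switch_fraction <= 1.0:
            raise ValueError("switch_fraction must be in [0, 1]")
        for lo, hi in (self.transcripts_per_gene, self.exons_per_transcript,
                       self.exon_length, self.intron_length):
            if lo <= 0 or hi < lo:
                raise ValueError("ranges must be positive with lo <= hi")
        if self.reads_distribution not in ("fixed", "poisson", "lognormal"):
            raise ValueError(f"unknown reads_distribution {self.reads_distribution!r}")


@dataclass
class SyntheticTruth:
    """Ground-truth manifest for one simulated dataset."""

    seed: int | None = None
    categories: dict[str, str] = field(default_factory=dict)
    gene_of: dict[str, str] = field(default_factory=dict)
    isoform_order: dict[str, list[str]] = field(default_factory=dict)
    switch_genes: list[str] = field(default_factory=list)
    usage: dict[str, dict[str, list[float]]] = field(default_factory=dict)
    novel_exons: list[tuple[str, int, int]] = field(default_factory=list)
    mean_reads: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["novel_exons"] = [tuple(x) for x in d.get("novel_exons", [])]
        return cls(**d)


# ===================================================================== reference


def _transcript_segments(
    exons: Sequence[GenomicInterval], strand: str, t_start: int, t_end: int
) -> list[tuple[int, int]]:
    """Genomic (start, end) segments covering transcript coordinates
    [t_start, t_end), returned in transcript (5'->3') order."""
    order = list(exons) if strand == "+" else list(exons)[::-1]
    segs: list[tuple[int, int]] = []
    pos = 0
    for e in order:
        lo, hi = max(t_start, pos), min(t_end, pos + e.length)
        if lo < hi:
            if strand == "+":
                segs.append((e.start + (lo - pos), e.start + (hi - pos)))
            else:
                segs.append((e.end - (hi - pos), e.end - (lo - pos)))
        pos += e.length
    return segs


def _cds_segments_with_frames(
    exons: Sequence[GenomicInterval], strand: str, t_start: int, t_end: int
) -> tuple[CdsSegment, ...]:
    segs = _transcript_segments(exons, strand, t_start, t_end)
    out, cum = [], 0
    for g0, g1 in segs:
        frame = (3 - cum % 3) % 3
        out.append(CdsSegment(GenomicInterval(exons[0].chrom, g0, g1, strand), frame))
        cum += g1 - g0
    return tuple(sorted(out, key=lambda s: s.interval.start))


def random_annotation(config: SimulationConfig, rng: np.random.Generator) -> GenomeAnnotation:
    """Build an in-memory annotation: non-overlapping genes on both strands,
    each with a master transcript (all exons, carrying a CDS) and optional
    alternate transcripts over consecutive exon windows."""
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    cursors = {c: config.gene_spacing for c in chrom_names}
    genes: list[Gene] = []
    for gi in range(config.n_genes):
        placed = False
        for _attempt in range(config.n_chromosomes * 4):
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            n_ex = int(rng.integers(config.exons_per_transcript[0], config.exons_per_transcript[1] + 1))
            exon_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, n_ex)
            intron_lens = rng.integers(config.intron_length[0], config.intron_length[1] + 1, max(n_ex - 1, 0))
            span = int(exon_lens.sum() + intron_lens.sum())
            start = cursors[chrom]
            if start + span + config.gene_spacing > config.chromosome_length:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"gene{gi + 1:03d}"
            exons = []
            pos = start
            for k in range(n_ex):
                exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[k]), strand))
                pos += int(exon_lens[k]) + (int(intron_lens[k]) if k < n_ex - 1 else 0)
            master = _make_master(gid, chrom, strand, exons, rng)
            transcripts = [master]
            n_t = int(rng.integers(config.transcripts_per_gene[0], config.transcripts_per_gene[1] + 1))
            used_windows = {(0, n_ex - 1)}
            for ti in range(n_t - 1):
                window = _alt_window(n_ex, used_windows, rng)
                if window is None:
                    break
                a, b = window
                used_windows.add(window)
                transcripts.append(
                    TranscriptModel(
                        id=f"{gid}.t{ti + 2}", chrom=chrom, strand=strand,
                        exons=tuple(exons[a : b + 1]), gene_id=gid,
                    )
                )
            genes.append(Gene(gid, chrom, strand, transcripts, name=gid.upper(), biotype="protein_coding"))
            cursors[chrom] = start + span + config.gene_spacing
            placed = True
            break
        if not placed:
            raise RuntimeError(
                "gene placement failed; increase chromosome_length or reduce n_genes"
            )
    return GenomeAnnotation(genes)


def _make_master(
    gid: str, chrom: str, strand: str, exons: list[GenomicInterval], rng: np.random.Generator
) -> TranscriptModel:
    # UTRs take up to ~40% of the spliced length each, so they frequently
    # span whole terminal exons (as in real annotations); the CDS occupies an
    # interior range.
    spliced_len = sum(e.length for e in exons)
    utr5 = int(rng.uniform(0.05, 0.4) * spliced_len)
    utr3 = int(rng.uniform(0.05, 0.4) * spliced_len)
    avail = spliced_len - utr5 - utr3
    cds_len = avail - avail % 3
    if cds_len < 60:
        utr5 = utr3 = (spliced_len - 66) // 2
        avail = spliced_len - utr5 - utr3
        cds_len = avail - avail % 3
    return TranscriptModel(
        id=f"{gid}.t1", chrom=chrom, strand=strand, exons=tuple(exons), gene_id=gid,
        cds=_cds_segments_with_frames(exons, strand, utr5, utr5 + cds_len),
    )


def _alt_window(n_ex: int, used: set[tuple[int, int]], rng: np.random.Generator) -> tuple[int, int] | None:
    if n_ex < 3:
        return None
    for _ in range(20):
        a = int(rng.integers(0, n_ex - 1))
        b = int(rng.integers(a + 1, n_ex))
        if (a, b) not in used:
            return (a, b)
    return None


def synthesize_genome(
    annotation: GenomeAnnotation, config: SimulationConfig, rng: np.random.Generator
) -> dict[str, str]:
    """Random genome sequence with every annotated CDS written in so it
    begins ATG, ends in a stop and contains no internal stop codons."""
    chroms = {
        f"chr{i + 1}": _BASES[rng.integers(0, 4, config.chromosome_length)]
        for i in range(config.n_chromosomes)
    }
    for tid in sorted(annotation.transcripts):
        t = annotation.transcripts[tid]
        if not t.cds:
            continue
        segs = sorted((s.interval for s in t.cds), key=lambda iv: iv.start)
        cds_len = sum(iv.length for iv in segs)
        n_codons = cds_len // 3
        codons = ["ATG"] + [
            _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 2)
        ] + [_STOPS[int(rng.integers(0, 3))]]
        coding = "".join(codons)
        positions: list[int] = []
        ordered = segs if t.strand == "+" else segs[::-1]
        for iv in ordered:
            if t.strand == "+":
                positions.extend(range(iv.start, iv.end))
            else:
                positions.extend(range(iv.end - 1, iv.start - 1, -1))
        arr = chroms[t.chrom]
        for pos, base in zip(positions, coding):
            arr[pos] = base if t.strand == "+" else _COMPLEMENT[base]
    return {c: "".join(arr) for c, arr in chroms.items()}


def generate_reference(
    config: SimulationConfig, seed: int | None = None, outdir: str | Path | None = None
) -> tuple[GenomeAnnotation, dict[str, str]]:
    """Deterministic reference (annotation + genome) for a config/seed; when
    ``outdir`` is given, ``annotation.gtf`` and ``genome.fa`` are written."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    annotation = random_annotation(config, rng)
    genome = synthesize_genome(annotation, config, rng)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        iio.write_annotation_gtf(annotation, outdir / "annotation.gtf")
        iio.write_fasta(genome, outdir / "genome.fa")
    return annotation, genome


# ===================================================================== isoforms


def _category_counts(n: int, mix: Sequence[float]) -> list[int]:
    counts = [int(round(f * n)) for f in mix]
    while sum(counts) > n:
        counts[counts.index(max(counts))] -= 1
    while sum(counts) < n:
        counts[counts.index(max(counts))] += 1
    return counts


class _AnnotationChecks:
    """Definitional checks used by the generator to certify each emitted
    model's truth category (chain identity, consecutive sub-chain, site
    membership, locus overlap)."""

    def __init__(self, annotation: GenomeAnnotation):
        self.ann = annotation

    def is_fsm(self, m: TranscriptModel) -> bool:
        return bool(self.ann.transcripts_with_chain(m))

    def is_ism(self, m: TranscriptModel) -> bool:
        chain = m.chain_key
        for tid, pos in self.ann.transcripts_containing_junction(m.junction_chain[0]):
            ref = self.ann.transcripts[tid].chain_key
            if len(ref) > len(chain) and ref[pos : pos + len(chain)] == chain:
                return True
        return False

    def all_sites_annotated(self, m: TranscriptModel) -> bool:
        return not self.ann.unannotated_sites(m)

    def overlaps_locus(self, m: TranscriptModel) -> bool:
        return bool(self.ann.genes_overlapping(m.span))


def generate_observed_isoforms(
    annotation: GenomeAnnotation,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[TranscriptModel], SyntheticTruth]:
    """Emit observed isoform models of each category with certified truth."""
    checks = _AnnotationChecks(annotation)
    truth = SyntheticTruth()
    models: list[TranscriptModel] = []
    wanted = _category_counts(config.n_observed_isoforms, config.category_mix)
    builders = {
        FSM: _build_fsm, ISM: _build_ism, NIC: _build_nic,
        NNC: _build_nnc, INTERGENIC: _build_intergenic,
    }
    gaps = _intergenic_gaps(annotation, config)
    counter = 0
    for category, n_cat in zip((FSM, ISM, NIC, NNC, INTERGENIC), wanted):
        for _ in range(n_cat):
            for _attempt in range(200):
                result = builders[category](annotation, config, rng, checks, gaps)
                if result is None:
                    continue
                model, gene_id, novel_exon = result
                counter += 1
                iso_id = f"iso_{counter:05d}"
                model = TranscriptModel(
                    id=iso_id, chrom=model.chrom, strand=model.strand, exons=model.exons,
                    gene_id=gene_id,
                )
                models.append(model)
                truth.categories[iso_id] = category
                truth.gene_of[iso_id] = gene_id if gene_id else f"intergenic_{iso_id}"
                if novel_exon is not None:
                    coords = (novel_exon.chrom, novel_exon.start, novel_exon.end)
                    if coords not in truth.novel_exons:
                        truth.novel_exons.append(coords)
                break
            else:
                raise RuntimeError(f"could not construct a {category} isoform; relax the config")
    return models, truth


def _random_multiexon_transcript(
    annotation: GenomeAnnotation, rng: np.random.Generator, min_exons: int = 2
) -> TranscriptModel:
    tids = sorted(t for t, m in annotation.transcripts.items() if m.n_exons >= min_exons)
    if not tids:
        raise RuntimeError(f"no reference transcript with >= {min_exons} exons")
    return annotation.transcripts[tids[int(rng.integers(0, len(tids)))]]


def _end_jitter(config, rng: np.random.Generator, outward_sign: int) -> int:
    """Signed genomic end offset: typically small (exponential), with a
    ``distant_end_fraction`` tail of outward extensions beyond 500 nt."""
    if rng.random() < config.distant_end_fraction:
        return outward_sign * int(rng.integers(520, config.end_jitter_max + 1))
    mag = min(int(rng.exponential(config.end_jitter_scale)), config.end_jitter_max)
    return mag if rng.random() < 0.5 else -mag


def _build_fsm(annotation, config, rng, checks, gaps):
    ref = _random_multiexon_transcript(annotation, rng, 2)
    exons = list(ref.exons)
    j5 = _end_jitter(config, rng, outward_sign=-1)
    j3 = _end_jitter(config, rng, outward_sign=+1)
    first, last = exons[0], exons[-1]
    new_start = int(np.clip(first.start + j5, 0, first.end - config.min_exon_length))
    new_end = int(np.clip(last.end + j3, last.start + config.min_exon_length, config.chromosome_length))
    exons[0] = GenomicInterval(first.chrom, new_start, first.end, first.strand)
    exons[-1] = GenomicInterval(last.chrom, last.start, new_end, last.strand)
    model = TranscriptModel(id="tmp", chrom=ref.chrom, strand=ref.strand, exons=tuple(exons))
    if not checks.is_fsm(model):  # cannot happen: jitter preserves the chain
        return None
    return model, annotation.gene_of_transcript[ref.id], None


def _build_ism(annotation, config, rng, checks, gaps):
    ref = _random_multiexon_transcript(annotation, rng, 3)
    n_j = len(ref.junction_chain)
    a = int(rng.integers(0, n_j))
    b = int(rng.integers(a, n_j))
    if (a, b) == (0, n_j - 1):
        return None
    exons = ref.exons[a : b + 2]
    model = TranscriptModel(id="tmp", chrom=ref.chrom, strand=ref.strand, exons=tuple(exons))
    if checks.is_fsm(model) or not checks.is_ism(model):
        return None
    return model, annotation.gene_of_transcript[ref.id], None


def _build_nic(annotation, config, rng, checks, gaps):
    # Exon skips recombine annotated sites into an unannotated chain. Most
    # real NIC events restructure noncoding ends (alternative TSS/UTR use),
    # so a configurable fraction skips an exon lying wholly outside the CDS.
    if rng.random() < config.nic_utr_fraction:
        masters = sorted(
            t for t, m in annotation.transcripts.items() if m.cds and m.n_exons >= 3
        )
        if not masters:
            return None
        ref = annotation.transcripts[masters[int(rng.integers(0, len(masters)))]]
        cds_lo = min(s.interval.start for s in ref.cds)
        cds_hi = max(s.interval.end for s in ref.cds)
        candidates = [
            i for i in range(1, ref.n_exons - 1)
            if ref.exons[i].end <= cds_lo or ref.exons[i].start >= cds_hi
        ]
        if not candidates:
            return None
        skip = candidates[int(rng.integers(0, len(candidates)))]
    else:
        ref = _random_multiexon_transcript(annotation, rng, 3)
        skip = int(rng.integers(1, ref.n_exons - 1))
    exons = tuple(e for i, e in enumerate(ref.exons) if i != skip)
    model = TranscriptModel(id="tmp", chrom=ref.chrom, strand=ref.strand, exons=exons)
    if checks.is_fsm(model) or checks.is_ism(model) or not checks.all_sites_annotated(model):
        return None
    return model, annotation.gene_of_transcript[ref.id], None


def _build_nnc(annotation, config, rng, checks, gaps):
    inject = rng.random() < config.novel_exon_fraction
    if inject:
        return _build_nnc_novel_exon(annotation, config, rng, checks)
    return _build_nnc_site_shift(annotation, config, rng, checks)


def _build_nnc_site_shift(annotation, config, rng, checks):
    ref = _random_multiexon_transcript(annotation, rng, 2)
    exons = list(ref.exons)
    k = int(rng.integers(0, len(exons) - 1))  # junction index: between exon k and k+1
    delta = int(rng.integers(5, 51)) * (1 if rng.random() < 0.5 else -1)
    e = exons[k]
    new_end = e.end + delta
    intron_end = exons[k + 1].start
    if not (e.start + config.min_exon_length <= new_end <= intron_end - 20):
        return None
    exons[k] = GenomicInterval(e.chrom, e.start, new_end, e.strand)
    model = TranscriptModel(id="tmp", chrom=ref.chrom, strand=ref.strand, exons=tuple(exons))
    if checks.is_fsm(model) or checks.is_ism(model) or checks.all_sites_annotated(model):
        return None
    return model, annotation.gene_of_transcript[ref.id], None


def _build_nnc_novel_exon(annotation, config, rng, checks):
    ref = _random_multiexon_transcript(annotation, rng, 2)
    exon_len = int(rng.integers(60, 121))
    margin = 50
    introns = [
        (i, ref.exons[i].end, ref.exons[i + 1].start)
        for i in range(ref.n_exons - 1)
        if ref.exons[i + 1].start - ref.exons[i].end >= exon_len + 2 * margin
    ]
    if not introns:
        return None
    i, lo, hi = introns[int(rng.integers(0, len(introns)))]
    start = int(rng.integers(lo + margin, hi - margin - exon_len + 1))
    new_exon = GenomicInterval(ref.chrom, start, start + exon_len, ref.strand)
    if annotation.exons_overlapping(new_exon):
        return None
    exons = list(ref.exons)
    exons.insert(i + 1, new_exon)
    model = TranscriptModel(id="tmp", chrom=ref.chrom, strand=ref.strand, exons=tuple(exons))
    if checks.is_fsm(model) or checks.is_ism(model) or checks.all_sites_annotated(model):
        return None
    return model, annotation.gene_of_transcript[ref.id], new_exon


def _intergenic_gaps(annotation: GenomeAnnotation, config: SimulationConfig) -> list[tuple[str, int, int]]:
    margin = 300
    gaps = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for g in annotation.genes.values():
        by_chrom.setdefault(g.chrom, []).append(g.span)
    for i in range(config.n_chromosomes):
        chrom = f"chr{i + 1}"
        spans = sorted(by_chrom.get(chrom, []), key=lambda s: s.start)
        prev = 0
        for s in spans:
            if s.start - prev >= 2 * margin + 400:
                gaps.append((chrom, prev + margin, s.start - margin))
            prev = max(prev, s.end)
        if config.chromosome_length - prev >= 2 * margin + 400:
            gaps.append((chrom, prev + margin, config.chromosome_length - margin))
    return gaps


def _build_intergenic(annotation, config, rng, checks, gaps):
    if not gaps:
        return None
    chrom, lo, hi = gaps[int(rng.integers(0, len(gaps)))]
    n_ex = int(rng.integers(2, 5))
    exon_lens = rng.integers(50, 150, n_ex)
    intron_lens = rng.integers(60, 200, n_ex - 1)
    span = int(exon_lens.sum() + intron_lens.sum())
    if hi - lo < span:
        return None
    start = int(rng.integers(lo, hi - span + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    exons, pos = [], start
    for k in range(n_ex):
        exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[k]), strand))
        pos += int(exon_lens[k]) + (int(intron_lens[k]) if k < n_ex - 1 else 0)
    model = TranscriptModel(id="tmp", chrom=chrom, strand=strand, exons=tuple(exons))
    if checks.overlaps_locus(model):
        return None
    return model, None, None


# ===================================================================== counts


def _switch_vectors(
    p0: np.ndarray, switch_usage: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Condition-group usage vectors for a switch gene: the two largest
    isoforms' combined mass is split ``switch_usage`` in group A and swapped
    in group B; other isoforms keep their null proportions."""
    order = np.argsort(p0)[::-1]
    i, j = int(order[0]), int(order[1])
    m = p0[i] + p0[j]
    p_a, p_b = p0.copy(), p0.copy()
    p_a[i], p_a[j] = switch_usage[0] * m, switch_usage[1] * m
    p_b[i], p_b[j] = switch_usage[1] * m, switch_usage[0] * m
    return p_a, p_b


def _gene_reads(config: SimulationConfig, rng: np.random.Generator) -> float:
    base = config.reads_per_gene_per_condition
    if config.reads_distribution == "fixed":
        return float(base)
    if config.reads_distribution == "poisson":
        return float(base)
    return float(rng.lognormal(math.log(base), config.reads_lognormal_sigma))


def simulate_counts(
    models: Sequence[TranscriptModel],
    truth: SyntheticTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
    all_genes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, SampleMap, pd.DataFrame]:
    """Per-sample isoform read counts, a sample map, and a gene RPM table.

    Per gene, a null usage vector is drawn from a symmetric Dirichlet; switch
    genes (a ``switch_fraction`` of multi-isoform genes) get the two-isoform
    usage swap between the first and second half of conditions. Counts per
    sample are multinomial draws. The truth manifest gains the switch list
    and the exact per-condition usage vectors.

    The RPM table mimics an independent short-read gene-expression assay:
    it covers the annotated genes in ``all_genes`` (when given), including
    genes for which no isoform was observed, and excludes unannotated
    intergenic loci.
    """
    conditions = [
        DEFAULT_CONDITIONS[i] if i < len(DEFAULT_CONDITIONS) else f"cond{i + 1}"
        for i in range(config.n_conditions)
    ]
    samples = [
        SampleInfo(f"{c}_rep{r + 1}", c, str(r + 1), True)
        for c in conditions for r in range(config.n_replicates)
    ]
    sample_map = SampleMap(samples)

    by_gene: dict[str, list[str]] = {}
    for m in models:
        by_gene.setdefault(truth.gene_of[m.id], []).append(m.id)
    genes = sorted(by_gene)
    eligible = [g for g in genes if len(by_gene[g]) >= 2]
    n_switch = min(len(eligible), int(round(config.switch_fraction * len(genes))))
    switch_genes = (
        sorted(rng.choice(eligible, size=n_switch, replace=False).tolist()) if n_switch else []
    )
    truth.switch_genes = switch_genes
    truth.isoform_order = {g: list(by_gene[g]) for g in genes}

    n_group_a = math.ceil(len(conditions) / 2)
    iso_ids = [m.id for m in models]
    counts = pd.DataFrame(
        0, index=iso_ids, columns=[s.sample for s in samples], dtype=np.int64
    )
    for g in genes:
        k = len(by_gene[g])
        p0 = rng.dirichlet(np.full(k, config.dirichlet_concentration)) if k > 1 else np.array([1.0])
        if g in switch_genes:
            p_a, p_b = _switch_vectors(p0, config.switch_usage)
        else:
            p_a = p_b = p0
        gene_mean = _gene_reads(config, rng)
        truth.mean_reads[g] = gene_mean
        truth.usage[g] = {}
        for ci, cond in enumerate(conditions):
            p = p_a if ci < n_group_a else p_b
            truth.usage[g][cond] = [float(x) for x in p]
            if config.reads_distribution == "fixed":
                n_cond = int(gene_mean)
            else:
                n_cond = int(rng.poisson(gene_mean))
            base, extra = divmod(n_cond, config.n_replicates)
            for r in range(config.n_replicates):
                n_rep = base + (1 if r < extra else 0)
                if n_rep == 0:
                    continue
                draw = rng.multinomial(n_rep, p)
                counts.loc[by_gene[g], f"{cond}_rep{r + 1}"] += draw
    gene_counts = counts.groupby(pd.Series(truth.gene_of)).sum()
    if all_genes is not None:
        # short-read expression covers annotated genes only; genes without an
        # observed isoform still show expression
        gene_counts = gene_counts.loc[[g for g in gene_counts.index if g in set(all_genes)]]
        missing = sorted(set(all_genes) - set(gene_counts.index))
        extra = {}
        for g in missing:
            gm = _gene_reads(config, rng)
            truth.mean_reads[g] = gm
            extra[g] = rng.poisson(gm / config.n_replicates, size=len(gene_counts.columns))
        if extra:
            gene_counts = pd.concat(
                [gene_counts, pd.DataFrame(extra, index=gene_counts.columns).T]
            ).sort_index()
    sample_totals = gene_counts.sum(axis=0).replace(0, 1)
    expression = gene_counts * 1e6 / sample_totals
    return counts, sample_map, expression


def null_usage_tables(
    rng: np.random.Generator,
    n_genes: int = 200,
    n_conditions: int = 4,
    n_isoforms: int = 3,
    concentration: float = 2.0,
    reads_per_condition: int = 100,
) -> list[UsageTable]:
    """Global-null isoform-by-condition tables: one shared usage vector per
    gene (Dirichlet), multinomial counts per condition."""
    tables = []
    for g in range(n_genes):
        p = rng.dirichlet(np.full(n_isoforms, concentration))
        m = np.stack(
            [rng.multinomial(reads_per_condition, p) for _ in range(n_conditions)], axis=1
        )
        tables.append(
            UsageTable(
                gene_id=f"gene{g + 1:04d}",
                isoform_ids=[f"gene{g + 1:04d}.i{k + 1}" for k in range(n_isoforms)],
                condition_ids=[f"cond{c + 1}" for c in range(n_conditions)],
                counts=m,
            )
        )
    return tables


def switch_usage_tables(
    rng: np.random.Generator,
    n_genes: int = 200,
    n_conditions: int = 4,
    n_isoforms: int = 2,
    concentration: float = 2.0,
    reads_per_condition: int = 500,
    n_switch: int = 20,
    switch_usage: tuple[float, float] = (0.8, 0.2),
) -> tuple[list[UsageTable], list[str]]:
    """Null tables with ``n_switch`` genes carrying a usage swap (group A
    conditions use ``switch_usage``, group B the reverse)."""
    tables = null_usage_tables(
        rng, n_genes, n_conditions, n_isoforms, concentration, reads_per_condition
    )
    switch_ids = sorted(
        rng.choice([t.gene_id for t in tables], size=n_switch, replace=False).tolist()
    )
    n_group_a = math.ceil(n_conditions / 2)
    for t in tables:
        if t.gene_id not in switch_ids:
            continue
        p0 = rng.dirichlet(np.full(n_isoforms, concentration))
        p_a, p_b = _switch_vectors(p0, switch_usage)
        cols = []
        for c in range(n_conditions):
            p = p_a if c < n_group_a else p_b
            cols.append(rng.multinomial(reads_per_condition, p))
        t.counts = np.stack(cols, axis=1)
    return tables, switch_ids


# ===================================================================== junctions


def emit_junctions(
    models: Sequence[TranscriptModel],
    dropout: float,
    rng: np.random.Generator,
) -> list[tuple[SpliceJunction, int]]:
    """Distinct junctions of the observed models, each dropped independently
    with probability ``dropout``; support counts are Poisson(20) + 1."""
    distinct = sorted(
        {j for m in models for j in m.junction_chain},
        key=lambda j: (j.chrom, j.intron_start, j.intron_end, j.strand),
    )
    out = []
    for j in distinct:
        if rng.random() < dropout:
            continue
        out.append((j, int(rng.poisson(20)) + 1))
    return out


# ===================================================================== dataset


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    annotation: GenomeAnnotation
    genome: dict[str, str]
    models: list[TranscriptModel]
    records: list[IsoformRecord]
    sample_map: SampleMap
    counts: pd.DataFrame
    expression: pd.DataFrame
    junctions: list[tuple[SpliceJunction, int]]
    truth: SyntheticTruth


def simulate_dataset(
    config: SimulationConfig,
    seed: int | None = None,
    outdir: str | Path | None = None,
) -> SimulatedDataset:
    """Run every generator stage from one seed; stage sub-seeds are derived
    deterministically so stages can be re-run independently."""
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rng_ref, rng_iso, rng_counts, rng_junc = (np.random.default_rng(c) for c in ss.spawn(4))

    annotation = random_annotation(config, rng_ref)
    genome = synthesize_genome(annotation, config, rng_ref)
    models, truth = generate_observed_isoforms(annotation, config, rng_iso)
    truth.seed = seed
    counts, sample_map, expression = simulate_counts(
        models, truth, config, rng_counts, all_genes=sorted(annotation.genes)
    )
    junctions = emit_junctions(models, config.junction_dropout, rng_junc)
    records = [
        IsoformRecord(model=m, counts={s: int(counts.loc[m.id, s]) for s in counts.columns})
        for m in models
    ]
    ds = SimulatedDataset(
        config, annotation, genome, models, records, sample_map,
        counts, expression, junctions, truth,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        iio.write_annotation_gtf(annotation, outdir / "annotation.gtf")
        iio.write_fasta(genome, outdir / "genome.fa")
        iio.write_models_gtf(models, outdir / "isoforms.gtf")
        counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="isoform")
        expression.to_csv(outdir / "expression.tsv", sep="\t", index_label="gene")
        with open(outdir / "samples.tsv", "w") as fh:
            fh.write("sample\tcondition\treplicate\tinclude\n")
            for s in sample_map.samples:
                fh.write(f"{s}\t{sample_map.condition_of(s)}\t{sample_map.replicate_of(s)}\t1\n")
        iio.write_sj_tab(junctions, outdir / "junctions.tsv")
        truth.to_json(outdir / "truth.json")
    return ds
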