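"""Readers and writers for GTF, BED12, FASTA, STAR SJ.out.tab, counts and sample maps.

Coordinate conventions: GTF and SJ.out.tab are 1-based inclusive on disk and
converted to the internal 0-based half-open convention here; BED is native
0-based half-open.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .annotation import (
    Gene,
    GenomeAnnotation,
    IsoformRecord,
    JunctionSet,
    SampleInfo,
    SampleMap,
)
from .intervals import CdsSegment, GenomicInterval, SpliceJunction, TranscriptModel

log = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "parse_gtf",
    "write_annotation_gtf",
    "write_models_gtf",
    "read_isoform_models",
    "read_sample_map",
    "read_short_read_junctions",
    "write_sj_tab",
    "load_genome",
    "spliced_sequence",
    "write_bed12",
    "write_fasta",
    "rpm_from_counts",
]


class ParseError(ValueError):
    """Raised for malformed input lines; carries file and line number."""


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _gtf_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def parse_gtf(path: str | Path, keep_biotypes: set[str] | None = None) -> GenomeAnnotation:
    """Parse a GENCODE-dialect GTF into an indexed :class:`GenomeAnnotation`.

    Only ``exon`` and ``CDS`` features are consumed; both must carry
    ``gene_id`` and ``transcript_id`` attributes. GTF 1-based inclusive
    coordinates become 0-based half-open. Records with end <= start are
    rejected and logged; structurally malformed lines raise
    :class:`ParseError` naming the line number.
    """
    path = Path(path)
    exons: dict[str, list[GenomicInterval]] = defaultdict(list)
    cds: dict[str, list[CdsSegment]] = defaultdict(list)
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (chrom, strand, gene_id)
    gene_meta: dict[str, dict[str, str | None]] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path.name}:{lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start_s, end_s, _score, strand, frame_s, attrs_s = fields[:9]
            if feature not in ("exon", "CDS"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: non-integer coordinates") from exc
            attrs = _gtf_attributes(attrs_s)
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise ParseError(f"{path.name}:{lineno}: missing gene_id/transcript_id attribute")
            if end1 < start1:  # zero/negative length after half-open conversion
                log.warning("%s:%d: rejected %s with end <= start", path.name, lineno, feature)
                continue
            biotype = attrs.get("gene_biotype") or attrs.get("gene_type")
            if keep_biotypes is not None and biotype is not None and biotype not in keep_biotypes:
                continue
            gid, tid = attrs["gene_id"], attrs["transcript_id"]
            start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
            meta.setdefault(tid, (chrom, strand, gid))
            gene_meta.setdefault(gid, {"name": attrs.get("gene_name"), "biotype": biotype})
            if feature == "exon":
                exons[tid].append(GenomicInterval(chrom, start, end, strand))
            else:
                frame = int(frame_s) if frame_s in ("0", "1", "2") else 0
                cds[tid].append(CdsSegment(GenomicInterval(chrom, start, end, strand), frame))

    genes: dict[str, Gene] = {}
    for tid, (chrom, strand, gid) in meta.items():
        if tid not in exons:
            log.warning("transcript %s has CDS but no exon features; skipped", tid)
            continue
        model = TranscriptModel(
            id=tid,
            chrom=chrom,
            strand=strand,
            exons=tuple(exons[tid]),
            gene_id=gid,
            cds=tuple(sorted(cds.get(tid, ()), key=lambda s: s.interval.start)),
        )
        gm = gene_meta[gid]
        gene = genes.setdefault(gid, Gene(gid, chrom, strand, [], gm["name"], gm["biotype"]))
        gene.transcripts.append(model)
    return GenomeAnnotation(genes.values())


def _gtf_lines(model: TranscriptModel, gene_id: str, name: str | None, biotype: str | None,
               source: str = "isokit") -> list[str]:
    attrs = f'gene_id "{gene_id}"; transcript_id "{model.id}";'
    if name:
        attrs += f' gene_name "{name}";'
    if biotype:
        attrs += f' gene_biotype "{biotype}";'
    lines = []
    for e in model.exons:
        lines.append(
            f"{model.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t{model.strand}\t.\t{attrs}"
        )
    for seg in model.cds:
        iv = seg.interval
        lines.append(
            f"{model.chrom}\t{source}\tCDS\t{iv.start + 1}\t{iv.end}\t.\t{model.strand}\t{seg.frame}\t{attrs}"
        )
    return lines


def write_annotation_gtf(annotation: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(annotation.genes):
            gene = annotation.genes[gid]
            for t in gene.transcripts:
                for line in _gtf_lines(t, gid, gene.name, gene.biotype):
                    fh.write(line + "\n")


def write_models_gtf(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write observed isoform models as an exon-only GTF."""
    with open(path, "w") as fh:
        for m in models:
            gid = m.gene_id or m.id
            for line in _gtf_lines(m, gid, None, None):
                fh.write(line + "\n")


# ----------------------------------------------------------------- isoform models


def _models_from_bed12(path: Path) -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ParseError(f"{path.name}:{lineno}: expected 12 BED columns")
            chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != len(starts):
                raise ParseError(f"{path.name}:{lineno}: blockSizes/blockStarts mismatch")
            exons = tuple(
                GenomicInterval(chrom, chrom_start + off, chrom_start + off + size, strand)
                for off, size in zip(starts, sizes)
            )
            models.append(TranscriptModel(id=name.split("|")[0], chrom=chrom, strand=strand, exons=exons))
    return models


def _models_from_gtf(path: Path) -> list[TranscriptModel]:
    ann = parse_gtf(path)
    return [ann.transcripts[tid] for tid in ann.transcripts]


def read_sample_map(path: str | Path) -> SampleMap:
    """Read a sample-map TSV with columns sample, condition[, replicate, include]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "sample" not in cols or "condition" not in cols:
        raise ParseError(f"{path}: sample map needs 'sample' and 'condition' columns")
    infos = []
    for _, row in df.iterrows():
        include = True
        if "include" in cols:
            include = str(row[cols["include"]]).strip().lower() in ("1", "true", "yes")
        infos.append(
            SampleInfo(
                sample=row[cols["sample"]],
                condition=row[cols["condition"]],
                replicate=str(row[cols["replicate"]]) if "replicate" in cols else "1",
                include=include,
            )
        )
    return SampleMap(infos)


def read_isoform_models(
    models_path: str | Path,
    counts_path: str | Path,
    sample_map: SampleMap | str | Path,
) -> list[IsoformRecord]:
    """Load isoform models (GTF or BED12) joined to a per-sample counts TSV.

    Every row id in the counts table must have a model; counts columns must
    all appear in the sample map. Records with zero total reads are kept
    (flagged via :attr:`IsoformRecord.zero_total`).
    """
    models_path = Path(models_path)
    if models_path.suffix.lower() == ".bed":
        models = _models_from_bed12(models_path)
    else:
        models = _models_from_gtf(models_path)
    by_id = {m.id: m for m in models}

    if not isinstance(sample_map, SampleMap):
        sample_map = read_sample_map(sample_map)

    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    missing = sorted(set(counts.index) - set(by_id))
    if missing:
        raise ParseError(f"count rows with no model: {', '.join(missing)}")
    unknown = sorted(set(counts.columns) - set(sample_map.samples))
    if unknown:
        raise ParseError(f"count columns not in sample map: {', '.join(unknown)}")
    if (counts.values < 0).any():
        raise ParseError("negative read counts in counts table")

    records = []
    for iso_id, row in counts.iterrows():
        rec = IsoformRecord(model=by_id[iso_id], counts={s: int(row[s]) for s in counts.columns})
        if rec.zero_total:
            log.info("isoform %s has zero total reads", iso_id)
        records.append(rec)
    return records


# ----------------------------------------------------------------- junctions

_SJ_STRAND = {"0": ".", "1": "+", "2": "-"}


def read_short_read_junctions(path: str | Path) -> JunctionSet:
    """Read splice junctions from a STAR SJ.out.tab-style TSV or a 6-column BED.

    SJ.out.tab intron coordinates are 1-based inclusive; column 7 (uniquely
    mapping reads) is the support count. BED6 is native half-open with the
    score column as support. Junctions with zero support are excluded;
    duplicate rows have their counts summed.
    """
    path = Path(path)
    js = JunctionSet()
    is_bed = path.suffix.lower() == ".bed"
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.rstrip("\n").split("\t")
            if is_bed:
                if len(f) < 6:
                    raise ParseError(f"{path.name}:{lineno}: expected 6 BED columns")
                chrom, start, end, count, strand = f[0], int(f[1]), int(f[2]), int(float(f[4])), f[5]
                if strand not in ("+", "-", "."):
                    log.warning("%s:%d: unknown strand %r treated as unstranded", path.name, lineno, strand)
                    strand = "."
            else:
                if len(f) < 7:
                    raise ParseError(f"{path.name}:{lineno}: expected >=7 SJ.out.tab columns")
                chrom = f[0]
                start, end = int(f[1]) - 1, int(f[2])  # 1-based inclusive -> half-open
                strand = _SJ_STRAND.get(f[3])
                if strand is None:
                    log.warning("%s:%d: unknown strand code %r treated as unstranded", path.name, lineno, f[3])
                    strand = "."
                count = int(f[6])
            if count <= 0:
                continue
            js.add(SpliceJunction(chrom, strand, start, end), count)
    return js


_SJ_CODE = {".": "0", "+": "1", "-": "2"}


def write_sj_tab(junctions: Iterable[tuple[SpliceJunction, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for j, count in junctions:
            fh.write(
                f"{j.chrom}\t{j.intron_start + 1}\t{j.intron_end}\t{_SJ_CODE[j.strand]}"
                f"\t0\t0\t{count}\t0\t20\n"
            )


# ----------------------------------------------------------------- sequence


def load_genome(path: str | Path):
    """Open an indexed FASTA for random access (builds the .fai on demand).

    The returned object can be passed wherever a genome mapping is expected
    (e.g. :func:`spliced_sequence`)."""
    from pyfaidx import Fasta

    return Fasta(str(path))


def spliced_sequence(model: TranscriptModel, genome: Mapping[str, object]) -> str:
    """Spliced transcript sequence: exon sequences concatenated in genomic
    order, reverse-complemented as a whole on the minus strand.

    ``genome`` is any mapping of chromosome name to a sliceable sequence
    (a dict of strings or a ``pyfaidx.Fasta``).
    """
    try:
        chrom_seq = genome[model.chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {model.chrom} absent from genome") from exc
    parts = [str(chrom_seq[e.start : e.end]) for e in model.exons]
    seq = "".join(parts).upper()
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


# ----------------------------------------------------------------- BED12 / FASTA


def write_bed12(
    records: Sequence[IsoformRecord],
    classifications: Mapping[str, object] | None,
    path: str | Path,
) -> None:
    """Export isoforms as BED12; the category (if given) is appended to the name."""
    with open(path, "w") as fh:
        fh.write('track name="isokit_isoforms"\n')
        for rec in records:
            m = rec.model
            start = m.span.start
            sizes = ",".join(str(e.length) for e in m.exons)
            offsets = ",".join(str(e.start - start) for e in m.exons)
            name = m.id
            if classifications is not None and m.id in classifications:
                cls = classifications[m.id]
                category = getattr(cls, "category", cls)
                name = f"{m.id}|{getattr(category, 'value', category)}"
            fh.write(
                f"{m.chrom}\t{start}\t{m.span.end}\t{name}\t{min(rec.total, 1000)}\t{m.strand}"
                f"\t{start}\t{start}\t0\t{m.n_exons}\t{sizes}\t{offsets}\n"
            )


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = str(genome[chrom])
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def rpm_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Reads-per-million normalization of a gene x sample raw-count table."""
    totals = counts.sum(axis=0)
    return counts * 1e6 / totals
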