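"""Independent brute-force oracles used to cross-check the implementation.

These enumerate definitions directly (all consecutive sub-chains of every
reference transcript, the full annotated site set, pairwise span overlap)
and deliberately share no logic with the package's indexed code paths.
"""

from __future__ import annotations

import numpy as np


def _chain(t):
    return [(j.intron_start, j.intron_end) for j in t.junction_chain]


def _spans_overlap(a, b):
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def oracle_classify(model, annotation) -> str:
    """Category by exhaustive enumeration of the definitions."""
    all_transcripts = [
        (g, t) for g in annotation.genes.values() for t in g.transcripts
    ]
    if model.n_exons == 1:
        exon = model.exons[0]
        for _g, t in all_transcripts:
            for e in t.exons:
                if e.chrom == exon.chrom and e.start <= exon.start and exon.end <= e.end:
                    return "mono_exon_known"
        if any(_spans_overlap(model.span, g.span) for g in annotation.genes.values()):
            return "mono_exon_genic"
        return "intergenic"

    mchain = _chain(model)
    same_strand = [
        t for _g, t in all_transcripts
        if t.chrom == model.chrom and t.strand == model.strand
    ]
    # FSM: identical chain
    if any(_chain(t) == mchain for t in same_strand):
        return "FSM"
    # ISM: consecutive proper sub-chain, enumerated exhaustively
    for t in same_strand:
        c = _chain(t)
        for i in range(len(c)):
            for j in range(i, len(c)):
                sub = c[i : j + 1]
                if len(sub) < len(c) and sub == mchain:
                    return "ISM"
    # intergenic: no locus overlap on either strand
    overlapping = [g for g in annotation.genes.values() if _spans_overlap(model.span, g.span)]
    if not overlapping:
        return "intergenic"
    # annotated site set on the model's chromosome and strand
    annotated = set()
    for t in same_strand:
        for s in t.splice_sites():
            annotated.add((s.position, s.side))
    model_sites = {(s.position, s.side) for s in model.splice_sites()}
    novel = model_sites - annotated
    if not any(g.strand == model.strand for g in overlapping) and novel == model_sites:
        return "genic_other"
    return "NIC" if not novel else "NNC"


def oracle_chi2(counts) -> tuple[float, int, float]:
    """Textbook Pearson chi-squared on a contingency table (no correction)."""
    from scipy.stats import chi2 as chi2_dist

    m = np.asarray(counts, dtype=float)
    m = m[m.sum(axis=1) > 0][:, m.sum(axis=0) > 0]
    n = m.sum()
    expected = np.outer(m.sum(axis=1), m.sum(axis=0)) / n
    stat = ((m - expected) ** 2 / expected).sum()
    df = (m.shape[0] - 1) * (m.shape[1] - 1)
    return float(stat), int(df), float(chi2_dist.sf(stat, df))


def oracle_overlap_components(spans):
    """Connected components of the pairwise span-overlap graph."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(spans)))
    for i in range(len(spans)):
        for j in range(i + 1, len(spans)):
            if _spans_overlap(spans[i], spans[j]):
                g.add_edge(i, j)
    return [sorted(c) for c in sorted(nx.connected_components(g), key=min)]
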