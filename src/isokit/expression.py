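"""Integration of short-read gene expression (RPM) with isoform detection.

Summarizes, per expression bin, how often the long-read workflow detected at
least one isoform for a gene, and how many isoforms it found per gene.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import IsoformClassification

DEFAULT_BIN_EDGES = (0.05, 3.0, 5.0, 10.0, 20.0, math.inf)


def mean_rpm(table: pd.DataFrame, samples: Sequence[str] | None = None) -> pd.Series:
    """Mean RPM per gene across the given samples (default: all columns)."""
    sub = table[list(samples)] if samples is not None else table
    return sub.mean(axis=1)


def expressed_genes(
    table: pd.DataFrame,
    min_mean_rpm: float = 0.05,
    samples: Sequence[str] | None = None,
) -> set[str]:
    """Genes with mean RPM strictly greater than ``min_mean_rpm``."""
    means = mean_rpm(table, samples)
    return set(means.index[means > min_mean_rpm])


def _bin_label(lo: float, hi: float) -> str:
    return f">{lo:g}" if math.isinf(hi) else f"{lo:g}-{hi:g}"


def assign_bins(
    means: pd.Series,
    genes: Iterable[str],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> dict[str, list[str]]:
    """Partition genes into lower-exclusive/upper-inclusive expression bins."""
    bins: dict[str, list[str]] = {
        _bin_label(lo, hi): [] for lo, hi in zip(bin_edges, bin_edges[1:])
    }
    for gene in genes:
        x = means[gene]
        for lo, hi in zip(bin_edges, bin_edges[1:]):
            if lo < x <= hi:
                bins[_bin_label(lo, hi)].append(gene)
                break
    return bins


def detection_rate_by_bin(
    table: pd.DataFrame,
    detected: set[str],
    min_mean_rpm: float = 0.05,
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    samples: Sequence[str] | None = None,
) -> dict[str, float]:
    """Per expression bin, the fraction of expressed genes with at least one
    detected isoform; empty bins report NaN (undefined, not zero)."""
    means = mean_rpm(table, samples)
    genes = expressed_genes(table, min_mean_rpm, samples)
    bins = assign_bins(means, genes, bin_edges)
    return {
        label: (sum(1 for g in members if g in detected) / len(members)) if members else math.nan
        for label, members in bins.items()
    }


def detected_gene_set(classifications: Mapping[str, IsoformClassification]) -> set[str]:
    """Genes with at least one classified isoform assigned to them."""
    return {c.assigned_gene for c in classifications.values() if c.assigned_gene is not None}


def isoforms_per_gene(
    classifications: Mapping[str, IsoformClassification],
) -> dict[str, int]:
    """Number of classified isoforms per assigned gene; isoforms without an
    assigned gene (intergenic) are excluded."""
    out: dict[str, int] = {}
    for c in classifications.values():
        if c.assigned_gene is not None:
            out[c.assigned_gene] = out.get(c.assigned_gene, 0) + 1
    return out


def isoforms_per_gene_by_bin(
    classifications: Mapping[str, IsoformClassification],
    table: pd.DataFrame,
    min_mean_rpm: float = 0.05,
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    samples: Sequence[str] | None = None,
) -> dict[str, dict[str, float]]:
    """Five-number summary (min, q1, median, q3, max) of isoforms-per-gene in
    each expression bin, over expressed genes with at least one isoform."""
    per_gene = isoforms_per_gene(classifications)
    means = mean_rpm(table, samples)
    genes = expressed_genes(table, min_mean_rpm, samples)
    bins = assign_bins(means, genes, bin_edges)
    out: dict[str, dict[str, float]] = {}
    for label, members in bins.items():
        values = np.array([per_gene[g] for g in members if g in per_gene], dtype=float)
        if values.size == 0:
            out[label] = {k: math.nan for k in ("min", "q1", "median", "q3", "max")}
        else:
            q1, med, q3 = np.percentile(values, [25, 50, 75])
            out[label] = {
                "min": float(values.min()),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "max": float(values.max()),
            }
    return out
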