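"""Differential isoform usage between conditions.

Per gene, isoform read counts are tabulated by condition; genes with at
least ``min_reads`` reads in at least ``min_conditions`` conditions are
tested with a chi-squared contingency test on the raw counts (no continuity
correction), p-values are Bonferroni-corrected over the number of genes
actually tested, and genes are ranked by p-value with the maximum per-isoform
usage standard deviation as the effect-size summary.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .annotation import IsoformRecord, SampleMap

log = logging.getLogger(__name__)


class UntestableGeneError(ValueError):
    """Gene has fewer than two non-degenerate rows or columns."""


@dataclass
class UsageTable:
    """Isoform x condition read counts for one gene."""

    gene_id: str
    isoform_ids: list[str]
    condition_ids: list[str]
    counts: np.ndarray  # shape (n_isoforms, n_conditions), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] < 1 or self.counts.shape[1] < 1:
            raise ValueError(f"{self.gene_id}: counts must be a non-empty 2-D matrix")
        if (self.counts < 0).any():
            raise ValueError(f"{self.gene_id}: negative counts")

    @property
    def condition_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def relative_usage(self) -> np.ndarray:
        """Percent usage per column; columns with zero total are NaN."""
        totals = self.condition_totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            usage = 100.0 * self.counts / totals
        usage[:, totals == 0] = np.nan
        return usage

    @property
    def testable_columns(self) -> np.ndarray:
        return self.condition_totals > 0


@dataclass
class DIUResult:
    gene_id: str
    n_isoforms: int
    n_conditions_tested: int
    chi2_stat: float
    df: int
    p_value: float
    p_bonferroni: float = np.nan
    significant: bool = False
    max_usage_sd: float = np.nan


def build_usage_table(
    gene_records: Sequence[IsoformRecord],
    sample_map: SampleMap,
    gene_id: str | None = None,
    collapse_replicates: bool = True,
) -> UsageTable:
    """Tabulate one gene's isoform counts per condition (default) or per
    sample. Samples excluded by the sample map's include flag never enter."""
    if not gene_records:
        raise ValueError("gene has zero isoforms")
    if collapse_replicates:
        columns = sample_map.conditions
        rows = [[rec.condition_totals(sample_map)[c] for c in columns] for rec in gene_records]
    else:
        columns = sample_map.included_samples
        rows = [[rec.counts.get(s, 0) for s in columns] for rec in gene_records]
    return UsageTable(
        gene_id=gene_id or gene_records[0].model.gene_id or "unknown",
        isoform_ids=[rec.id for rec in gene_records],
        condition_ids=list(columns),
        counts=np.array(rows, dtype=np.int64),
    )


def filter_testable_genes(
    tables: Iterable[UsageTable],
    min_reads: int = 50,
    min_conditions: int = 2,
) -> list[UsageTable]:
    """Keep genes with at least ``min_reads`` reads in at least
    ``min_conditions`` conditions (both bounds inclusive)."""
    return [
        t for t in tables
        if int((t.condition_totals >= min_reads).sum()) >= min_conditions
    ]


def chi2_contingency_test(counts: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-squared contingency test on raw counts.

    All-zero rows and columns are dropped first; fewer than 2x2 remaining
    raises :class:`UntestableGeneError`. No continuity correction. A warning
    is logged when any expected count falls below 5 (the read-count filter
    is the only small-count guard in this workflow).
    """
    m = np.asarray(counts, dtype=float)
    if m.ndim != 2:
        raise UntestableGeneError("counts must be a 2-D matrix")
    if m.size:
        m = m[m.sum(axis=1) > 0][:, m.sum(axis=0) > 0]
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise UntestableGeneError("need >=2 non-degenerate rows and columns")
    stat, p, df, expected = stats.chi2_contingency(m, correction=False)
    if (expected < 5).any():
        # deduplicated by the default warnings filter; the >=50-reads filter
        # is the workflow's only hard small-count guard
        warnings.warn("chi-squared test with expected counts < 5", RuntimeWarning, stacklevel=2)
    return float(stat), int(df), float(p)


def bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni adjustment over the tests actually performed.

    Returns ``(p_adjusted, significant)`` with ``p_adj = min(1, p * m)`` and
    significance declared when ``p_adj < alpha``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    p_adj = np.minimum(1.0, p * p.size)
    return p_adj, p_adj < alpha


def max_usage_sd(table: UsageTable) -> float:
    """Maximum over isoforms of the population standard deviation of relative
    usage (percentage points) across conditions with nonzero totals."""
    cols = table.testable_columns
    if int(cols.sum()) < 2:
        raise UntestableGeneError("max_usage_sd needs >=2 conditions with reads")
    usage = table.relative_usage[:, cols]
    return float(np.max(np.std(usage, axis=1)))  # ddof=0: population SD


def run_diu_tables(
    tables: Sequence[UsageTable],
    alpha: float = 0.05,
    min_reads: int = 50,
    min_conditions: int = 2,
) -> tuple[list[DIUResult], list[str]]:
    """Filter -> test -> Bonferroni -> rank on prebuilt usage tables.

    Returns the ranked results (p ascending, then max usage SD descending,
    then gene id) and the ids of genes that passed the read filter but were
    untestable (e.g. a single isoform)."""
    testable = filter_testable_genes(tables, min_reads=min_reads, min_conditions=min_conditions)
    results: list[DIUResult] = []
    untestable: list[str] = []
    for t in testable:
        try:
            stat, df, p = chi2_contingency_test(t.counts)
        except UntestableGeneError:
            untestable.append(t.gene_id)
            continue
        results.append(
            DIUResult(
                gene_id=t.gene_id,
                n_isoforms=len(t.isoform_ids),
                n_conditions_tested=int(t.testable_columns.sum()),
                chi2_stat=stat,
                df=df,
                p_value=p,
                max_usage_sd=max_usage_sd(t),
            )
        )
    p_adj, sig = bonferroni([r.p_value for r in results], alpha=alpha)
    for r, pa, s in zip(results, p_adj, sig):
        r.p_bonferroni = float(pa)
        r.significant = bool(s)
    results.sort(key=lambda r: (r.p_value, -r.max_usage_sd, r.gene_id))
    return results, untestable


def run_diu(
    records: Sequence[IsoformRecord],
    sample_map: SampleMap,
    gene_of: Mapping[str, str | None],
    alpha: float = 0.05,
    min_reads: int = 50,
    min_conditions: int = 2,
    collapse_replicates: bool = True,
) -> tuple[list[DIUResult], list[str]]:
    """Full differential-isoform-usage workflow from isoform records.

    ``gene_of`` maps isoform id to assigned gene (isoforms mapping to None,
    e.g. intergenic, are excluded)."""
    by_gene: dict[str, list[IsoformRecord]] = defaultdict(list)
    for rec in records:
        gene = gene_of.get(rec.id)
        if gene is not None:
            by_gene[gene].append(rec)
    tables = [
        build_usage_table(recs, sample_map, gene_id=gene, collapse_replicates=collapse_replicates)
        for gene, recs in sorted(by_gene.items())
    ]
    return run_diu_tables(tables, alpha=alpha, min_reads=min_reads, min_conditions=min_conditions)
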