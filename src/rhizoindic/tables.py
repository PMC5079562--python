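"""Taxon count tables: per-rank aggregation, unspecific-group filtering,
percentage conversion, composition summaries and common-taxa analysis.

The central container is :class:`TaxonCountTable`: a taxa x samples matrix
of read counts where every row carries a full lineage over the seven
Linnaean ranks. Rows can be rolled up to any rank (counts are summed over
shared lineage prefixes, so per-sample totals are conserved), cleaned of
"unspecific" catch-all groups (labels like "unclassified" or
"environmental samples", plus non-bacterial domains) and converted to
percent composition. Two cross-sample summaries mirror standard soil-16S
reporting: per-taxon mean percent with normalized standard deviation
(NSD = sigma / mean, the coefficient of variation), and the common-taxa
analysis — union and intersection of detected taxa across the samples
retained at a minimum-read threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, EmptySampleError, EmptySelectionError, InsufficientDataError

__all__ = [
    "RANKS",
    "UNSPECIFIC_LABELS",
    "TaxonCountTable",
    "CompositionSummary",
    "CommonTaxaResult",
    "aggregate_to_level",
    "filter_unspecific",
    "to_percentages",
    "composition_summary",
    "common_taxa",
]

#: The seven ranks a lineage spans, from coarsest to finest.
RANKS: tuple[str, ...] = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: Catch-all labels that pool reads from heterogeneous groups; excluded from
#: between-sample comparisons.
UNSPECIFIC_LABELS: frozenset[str] = frozenset(
    {"environmental samples", "unclassified", "No hits", "Not assigned"}
)

LINEAGE_SEP = ";"


def _rank_index(level: str) -> int:
    try:
        return RANKS.index(level)
    except ValueError:
        raise DomainError(f"unknown rank {level!r}; expected one of {RANKS}") from None


@dataclass
class TaxonCountTable:
    """Taxa x samples count matrix with rank-labelled lineages.

    ``counts`` is indexed by the semicolon-joined lineage; ``lineages``
    shares that index and has one column per rank down to ``level``.
    """

    counts: pd.DataFrame
    lineages: pd.DataFrame
    level: str = "species"

    def __post_init__(self) -> None:
        _rank_index(self.level)
        if not self.counts.index.equals(self.lineages.index):
            raise DomainError("counts and lineages must share a row index")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise DomainError("row and column labels must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise DomainError("counts must be non-negative")

    @classmethod
    def from_lineages(
        cls,
        lineages: Sequence[Sequence[str]],
        counts: np.ndarray | Sequence[Sequence[int]],
        samples: Sequence[str],
        level: str = "species",
    ) -> "TaxonCountTable":
        """Build a table from per-taxon lineage tuples and a count matrix.

        Rows with identical full lineages (e.g. several taxa pooled into
        the same "unclassified" bin) are merged by summing their counts.
        """
        depth = _rank_index(level) + 1
        lin = pd.DataFrame(list(lineages), columns=list(RANKS[:depth]))
        idx = pd.Index(
            [LINEAGE_SEP.join(row) for row in lin.itertuples(index=False)], name="lineage"
        )
        lin.index = idx
        cnt = pd.DataFrame(np.asarray(counts), index=idx, columns=list(samples))
        if idx.has_duplicates:
            cnt = cnt.groupby(level=0, sort=False).sum()
            lin = lin.groupby(level=0, sort=False).first()
            lin = lin.loc[cnt.index]
        return cls(counts=cnt, lineages=lin, level=level)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def domains(self) -> pd.Series:
        """Domain of each row, read off the kingdom label."""
        return self.lineages["kingdom"]


def aggregate_to_level(table: TaxonCountTable, level: str) -> TaxonCountTable:
    """Sum rows sharing the lineage prefix up to ``level``.

    Aggregating to the table's own (or a finer stored) level is the
    identity up to row ordering; per-sample totals are always conserved.
    """
    depth = _rank_index(level) + 1
    have = _rank_index(table.level) + 1
    if depth > have:
        raise DomainError(
            f"table is resolved at {table.level!r}; cannot refine to {level!r}"
        )
    if depth == have:
        return replace(table)
    keys = list(RANKS[:depth])
    joined = table.counts.join(table.lineages[keys])
    grouped = joined.groupby(keys, sort=False).sum(numeric_only=True)
    lin = grouped.index.to_frame(index=False)
    if depth == 1:  # groupby on a single key yields a flat index
        lin.columns = keys
    idx = pd.Index(
        [LINEAGE_SEP.join(row) for row in lin.itertuples(index=False)], name="lineage"
    )
    lin.index = idx
    cnt = pd.DataFrame(grouped.to_numpy(), index=idx, columns=table.counts.columns)
    return TaxonCountTable(counts=cnt, lineages=lin, level=level)


def filter_unspecific(table: TaxonCountTable, level: str | None = None) -> TaxonCountTable:
    """Drop unspecific rows and non-bacterial lineages.

    A row is removed if its label at ``level`` (default: the table's own
    resolution) belongs to :data:`UNSPECIFIC_LABELS`, or if its domain is
    not Bacteria. May return an empty table.
    """
    level = table.level if level is None else level
    depth = _rank_index(level) + 1
    if depth > _rank_index(table.level) + 1:
        raise DomainError(f"table has no {level!r} column to filter on")
    bad = table.lineages[level].isin(UNSPECIFIC_LABELS) | (table.domains != "Bacteria")
    keep = ~bad
    return TaxonCountTable(
        counts=table.counts.loc[keep],
        lineages=table.lineages.loc[keep],
        level=table.level,
    )


def to_percentages(table: TaxonCountTable) -> pd.DataFrame:
    """Scale each sample column to sum to 100."""
    totals = table.sample_totals
    zero = totals[totals <= 0]
    if len(zero):
        raise EmptySampleError(
            f"zero-total sample column(s) after filtering: {list(zero.index)}"
        )
    return table.counts.div(totals, axis=1) * 100.0


@dataclass(frozen=True)
class CompositionSummary:
    """Cross-sample composition of one taxon at one rank."""

    taxon: str
    level: str
    mean_percent: float
    sd: float
    nsd: float  # sigma / mean; NaN flags an undefined value (mean = 0)


def composition_summary(percents: pd.DataFrame, level: str) -> list[CompositionSummary]:
    """Per-taxon mean percent, sample SD and NSD across sample columns.

    A taxon absent from a sample contributes 0% in that sample. NSD is
    flagged undefined (NaN) for taxa whose mean is zero.
    """
    _rank_index(level)
    if percents.shape[1] < 2:
        raise InsufficientDataError("need >= 2 samples for a composition summary")
    mean = percents.mean(axis=1)
    sd = percents.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        nsd = np.where(mean > 0, sd / mean, np.nan)
    return [
        CompositionSummary(taxon=t, level=level, mean_percent=float(m), sd=float(s), nsd=float(n))
        for t, m, s, n in zip(percents.index, mean, sd, nsd)
    ]


@dataclass(frozen=True)
class CommonTaxaResult:
    """Union/intersection of clearly-identified taxa over retained samples."""

    level: str
    min_sample_reads: int
    retained_samples: tuple[str, ...]
    union: frozenset[str]
    intersection: frozenset[str]

    @property
    def n_union(self) -> int:
        return len(self.union)

    @property
    def n_common(self) -> int:
        return len(self.intersection)


def common_taxa(
    table: TaxonCountTable, min_sample_reads: int, level: str
) -> CommonTaxaResult:
    """Identify taxa detected in, and common to, the sufficiently-deep samples.

    Samples whose *raw* total reads exceed ``min_sample_reads`` (strict)
    are retained; the table is rolled up to ``level`` and stripped of
    unspecific / non-bacterial rows; the result reports the union of taxa
    detected in any retained sample and the intersection (count > 0 in
    every retained sample).
    """
    if min_sample_reads < 0:
        raise DomainError("min_sample_reads must be >= 0")
    totals = table.sample_totals
    retained = [s for s in table.samples if totals[s] > min_sample_reads]
    if not retained:
        raise EmptySelectionError(
            f"no sample has more than {min_sample_reads} reads"
        )
    leveled = filter_unspecific(aggregate_to_level(table, level), level)
    sub = leveled.counts[retained]
    present = sub > 0
    union = frozenset(sub.index[present.any(axis=1)])
    intersection = frozenset(sub.index[present.all(axis=1)])
    return CommonTaxaResult(
        level=level,
        min_sample_reads=min_sample_reads,
        retained_samples=tuple(retained),
        union=union,
        intersection=intersection,
    )
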