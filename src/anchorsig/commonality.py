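"""Cross-dataset commonality: tally, rank, truncate and slice DE gene lists.

Given the per-dataset DE gene lists that survived the anchor gate, this stage
builds a gene x dataset membership matrix, counts for each gene the number of
datasets containing it, ranks genes by that count (ties broken alphabetically
for determinism), truncates the ranking to a top-N list, and slices the
matrix at "common to at least k datasets" levels. Slices are computed from
the full matrix by default so they do not depend on the truncation size; pass
``from_ranked`` to restrict a slice to the truncated list instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from ._utils import normalize_symbols
from .errors import ValidationError

DEFAULT_TOP_N = 1000


@dataclass
class CommonalityMatrix:
    """Boolean gene x dataset membership with per-gene dataset counts."""

    member: pd.DataFrame  # bool, index = genes (sorted), columns = dataset ids

    @property
    def genes(self) -> list[str]:
        return list(self.member.index)

    @property
    def datasets(self) -> list[str]:
        return list(self.member.columns)

    @property
    def counts(self) -> pd.Series:
        return self.member.sum(axis=1).astype(int)


@dataclass
class RankedList:
    """Genes ordered by (dataset count desc, symbol asc), truncated to top_n."""

    table: pd.DataFrame  # columns: gene, count, rank (1-based)
    top_n: int

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])


def build_matrix(lists: Mapping[str, set[str]]) -> CommonalityMatrix:
    """Assemble the membership matrix from per-dataset DE gene sets.

    Empty lists are skipped with no contribution; at least one non-empty list
    is required.
    """
    usable = {str(d): normalize_symbols(genes) for d, genes in lists.items()}
    usable = {d: g for d, g in usable.items() if g}
    if not usable:
        raise ValidationError("build_matrix: no non-empty DE lists supplied")
    all_genes = sorted(set().union(*usable.values()))
    data = {
        d: [g in members for g in all_genes]
        for d, members in sorted(usable.items())
    }
    member = pd.DataFrame(data, index=all_genes, dtype=bool)
    return CommonalityMatrix(member)


def rank_genes(m: CommonalityMatrix, top_n: int = DEFAULT_TOP_N) -> RankedList:
    """Sort genes by dataset count (descending, symbol ascending) and truncate."""
    if top_n < 1:
        raise ValidationError("top_n: must be positive")
    counts = m.counts
    table = (
        pd.DataFrame({"gene": counts.index, "count": counts.to_numpy()})
        .sort_values(["count", "gene"], ascending=[False, True], kind="mergesort")
        .head(top_n)
        .reset_index(drop=True)
    )
    table["rank"] = range(1, len(table) + 1)
    return RankedList(table, top_n)


def slice_at(m: CommonalityMatrix, k: int,
             from_ranked: RankedList | None = None) -> set[str]:
    """Genes present in at least ``k`` datasets (from the full matrix).

    If ``from_ranked`` is given, the slice is additionally restricted to the
    genes of that truncated ranking.
    """
    if not 1 <= k <= len(m.datasets):
        raise ValidationError(
            f"k: must lie in [1, {len(m.datasets)}] for this matrix"
        )
    counts = m.counts
    genes = set(counts.index[counts >= k])
    if from_ranked is not None:
        genes &= set(from_ranked.genes)
    return genes


def level_counts(m: CommonalityMatrix) -> dict[int, int]:
    """Histogram of genes per exact dataset count, 1..n_datasets, zeros kept."""
    counts = m.counts.value_counts()
    return {k: int(counts.get(k, 0)) for k in range(1, len(m.datasets) + 1)}
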