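"""Readers and writers for every on-disk artifact of the pipeline.

Formats handled
---------------
expression matrix  TSV; first column = gene symbol, header row = sample ids
group sidecar      two-column TSV ``sample<TAB>group``, groups ``control``/``case``
gene sets          GMT (set name, description, tab-separated members)
interactions       SIF (``nodeA<TAB>interaction<TAB>nodeB``) or two-column TSV
gene lists         plain text, one symbol per line
reports            JSON (sorted keys, so identical content means identical bytes)

All parsers are strict about structure (a malformed line raises
:class:`~anchorsig.errors.FormatError` naming the line) but lenient about the
case and surrounding whitespace of gene symbols, which are normalized to
stripped upper case everywhere.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from ._utils import normalize_symbol, normalize_symbols
from .errors import FormatError, ValidationError

GROUPS = ("control", "case")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """One two-group log2 expression matrix with sample-to-group labels.

    Parameters
    ----------
    dataset_id : str
        Identifier of the series the matrix came from.
    values : pandas.DataFrame
        genes x samples matrix of log2 expression; the index holds gene
        symbols (normalized on construction), the columns sample ids.
    group_of : dict
        Maps every sample id to ``"control"`` or ``"case"``.
    """

    dataset_id: str
    values: pd.DataFrame
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        self.values = self.values.copy()
        self.values.index = [normalize_symbol(g) for g in self.values.index.astype(str)]
        if self.values.index.has_duplicates:
            dups = sorted(self.values.index[self.values.index.duplicated()].unique())
            raise ValidationError(
                f"dataset '{self.dataset_id}': duplicate gene symbols after "
                f"normalization: {dups[:5]}"
            )
        try:
            self.values = self.values.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"dataset '{self.dataset_id}': non-numeric expression values"
            ) from exc
        if self.values.isna().any().any():
            raise ValidationError(f"dataset '{self.dataset_id}': missing expression values")
        self.group_of = {str(s): str(g).strip().lower() for s, g in self.group_of.items()}
        for sample in self.values.columns:
            grp = self.group_of.get(sample)
            if grp is None:
                raise ValidationError(
                    f"dataset '{self.dataset_id}': sample '{sample}' has no group label"
                )
            if grp not in GROUPS:
                raise ValidationError(
                    f"dataset '{self.dataset_id}': sample '{sample}' has unknown "
                    f"group '{grp}' (expected control/case)"
                )
        for grp in GROUPS:
            if not any(self.group_of.get(s) == grp for s in self.values.columns):
                raise ValidationError(
                    f"dataset '{self.dataset_id}': group '{grp}' has no samples"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.group_of[s] == "control"]

    @property
    def case_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.group_of[s] == "case"]


@dataclass
class GeneSetCollection:
    """A named collection of gene sets (a GMT file in memory)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normed: dict[str, frozenset[str]] = {}
        for sid, members in self.sets.items():
            members = frozenset(normalize_symbols(members))
            if not members:
                raise ValidationError(f"gene set '{sid}' is empty after normalization")
            normed[str(sid)] = members
        self.sets = normed

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, sid: str) -> frozenset[str]:
        return self.sets[sid]

    def ids(self) -> list[str]:
        return sorted(self.sets)


@dataclass
class InteractionGraph:
    """An undirected simple protein-protein interaction graph."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValidationError(f"interaction graph has self-loops: {loops[:5]}")

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]],
                   nodes: Iterable[str] = ()) -> "InteractionGraph":
        g = nx.Graph()
        g.add_nodes_from(normalize_symbol(n) for n in nodes)
        for a, b in edges:
            a, b = normalize_symbol(a), normalize_symbol(b)
            if a == b:
                warnings.warn(f"self-loop on '{a}' ignored")
                continue
            g.add_edge(a, b)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _read_groups_sidecar(path: str | Path) -> dict[str, str]:
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected two tab-separated columns "
                    f"(sample, group), got {len(parts)}"
                )
            rows.append([p.strip() for p in parts])
    if rows and [r.lower() for r in rows[0]] == ["sample", "group"]:
        rows = rows[1:]
    return {sample: group for sample, group in rows}


def read_expression(matrix_path: str | Path, groups_path: str | Path,
                    dataset_id: str | None = None) -> ExpressionDataset:
    """Read one expression TSV plus its sample-to-group sidecar.

    Duplicate gene rows (after symbol normalization) are collapsed by their
    mean with a warning. A sample present in the matrix but absent from the
    sidecar is an error naming that sample.
    """
    matrix_path = Path(matrix_path)
    if dataset_id is None:
        dataset_id = matrix_path.stem
    try:
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{matrix_path}: could not parse TSV: {exc}") from exc
    df.index = [normalize_symbol(g) for g in df.index.astype(str)]
    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        warnings.warn(
            f"{matrix_path}: {n_dup} duplicate gene row(s) collapsed by mean"
        )
        df = df.groupby(level=0, sort=False).mean()
    groups = _read_groups_sidecar(groups_path)
    missing = [s for s in df.columns if s not in groups]
    if missing:
        raise ValidationError(
            f"{groups_path}: sample '{missing[0]}' missing from group sidecar"
        )
    group_of = {s: groups[s] for s in df.columns}
    return ExpressionDataset(dataset_id, df, group_of)


def write_expression(ds: ExpressionDataset, matrix_path: str | Path,
                     groups_path: str | Path) -> None:
    ds.values.to_csv(matrix_path, sep="\t", index_label="gene")
    with open(groups_path, "w") as fh:
        fh.write("sample\tgroup\n")
        for sample in ds.sample_ids:
            fh.write(f"{sample}\t{ds.group_of[sample]}\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>member...`` per line."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs a name, a description "
                    f"and at least one member"
                )
            name = parts[0].strip()
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set id '{name}'")
            members = frozenset(normalize_symbols(parts[2:]))
            if not members:
                raise FormatError(f"{path}:{lineno}: set '{name}' has no members")
            sets[name] = members
            descriptions[name] = parts[1].strip()
    if not sets:
        warnings.warn(f"{path}: empty GMT file, returning empty collection")
    return GeneSetCollection(sets, descriptions)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid in coll.ids():
            desc = coll.descriptions.get(sid, "")
            members = "\t".join(sorted(coll.sets[sid]))
            fh.write(f"{sid}\t{desc}\t{members}\n")


# ---------------------------------------------------------------------------
# interaction edge lists (SIF / two-column TSV)
# ---------------------------------------------------------------------------

def read_edges(path: str | Path) -> InteractionGraph:
    """Read an interactome from SIF or a two-column TSV edge list.

    The SIF interaction type is ignored; reverse-duplicate edges are merged;
    self-loops are dropped with a warning.
    """
    g = nx.Graph()
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) == 3:
                a, b = parts[0], parts[2]
            elif len(parts) == 2:
                a, b = parts
            else:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 (edge list) or 3 (SIF) "
                    f"columns, got {len(parts)}"
                )
            n_lines += 1
            a, b = normalize_symbol(a), normalize_symbol(b)
            if a == b:
                warnings.warn(f"{path}:{lineno}: self-loop on '{a}' ignored")
                continue
            g.add_edge(a, b)
    if n_lines == 0:
        warnings.warn(f"{path}: empty edge file, returning empty graph")
    return InteractionGraph(g)


def write_sif(graph: InteractionGraph, path: str | Path,
              interaction: str = "pp") -> None:
    with open(path, "w") as fh:
        for a, b in sorted(graph.edges):
            fh.write(f"{a}\t{interaction}\t{b}\n")


# ---------------------------------------------------------------------------
# plain gene lists and JSON reports
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path) -> set[str]:
    """Read a plain gene list, one symbol per line (blank lines skipped)."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            sym = normalize_symbol(line)
            if sym:
                out.add(sym)
    if not out:
        warnings.warn(f"{path}: empty gene list")
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(normalize_symbols(genes)):
            fh.write(g + "\n")


def write_json(obj: Mapping, path: str | Path) -> None:
    """Write a JSON report with sorted keys and a trailing newline."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
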