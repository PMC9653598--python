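"""Synthetic study generator: every input the pipeline needs, with planted signal.

Real analyses of this kind start from a panel of public two-group expression
series, a pathway collection, a curated reference gene set and an interactome,
all fetched from external services. This module generates local stand-ins for
each of those inputs with a known planted structure, so that every downstream
stage (differential expression, commonality ranking, enrichment, overlap
testing, subnetwork extraction) can be exercised and validated offline:

* :func:`generate_dataset` - a two-group log2 expression matrix in which an
  anchor gene and a module of partner genes carry a shared expression shift;
* :func:`generate_gmt` - a random gene-set collection containing one planted
  pathway;
* :func:`generate_reference_set` - a reference ("aging-like") gene set with a
  controlled excess overlap against an enriched pool;
* :func:`generate_ppi` - an interaction graph with planted cliques on top of
  sparse background edges.

All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._utils import normalize_symbol, substream
from .errors import ValidationError
from .io import ExpressionDataset, GeneSetCollection, InteractionGraph

#: default size of the planted co-regulated module
_DEFAULT_MODULE_SIZE = 50

#: log2 magnitude range of independent background differential expression
_BACKGROUND_SHIFT_RANGE = (1.0, 2.0)


def _default_module() -> tuple[str, ...]:
    return tuple(f"GM{i + 1:03d}" for i in range(_DEFAULT_MODULE_SIZE))


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions of one simulated multi-dataset two-group study.

    Attributes
    ----------
    n_genes : int
        Total genes per dataset (anchor + module + background fillers).
    n_per_group : int
        Samples per condition (control and case).
    anchor : str
        Symbol of the gene whose differential expression gates each dataset.
    module_genes : tuple of str
        Genes co-regulated with the anchor.
    effect_size : float
        Mean log2 shift added to the case group for the anchor and module;
        the sign encodes the direction of anchor regulation.
    noise_sd : float
        Per-observation Gaussian standard deviation, log2 units.
    background_de_fraction : float
        Fraction of non-module genes given an independent random shift,
        resampled per dataset.
    n_datasets : int
        Number of datasets in the simulated panel.
    module_penetrance : float
        Per-dataset probability that each module gene carries the shift.
    seed : int
        Root RNG seed; together with a dataset index it fully determines
        each generated matrix.
    """

    n_genes: int = 5000
    n_per_group: int = 10
    anchor: str = "GPR19"
    module_genes: tuple[str, ...] = field(default_factory=_default_module)
    effect_size: float = 2.0
    noise_sd: float = 1.0
    background_de_fraction: float = 0.05
    n_datasets: int = 7
    module_penetrance: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "anchor", normalize_symbol(self.anchor))
        module = tuple(normalize_symbol(g) for g in self.module_genes)
        object.__setattr__(self, "module_genes", module)
        if self.n_per_group < 2:
            raise ValidationError("n_per_group: need at least 2 samples per group")
        if not 0.0 <= self.module_penetrance <= 1.0:
            raise ValidationError("module_penetrance: must lie in [0, 1]")
        if not 0.0 <= self.background_de_fraction <= 1.0:
            raise ValidationError("background_de_fraction: must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd: must be non-negative")
        if self.n_datasets < 1:
            raise ValidationError("n_datasets: must be positive")
        if self.anchor in module:
            raise ValidationError("module_genes: anchor must not be a module gene")
        if len(set(module)) != len(module):
            raise ValidationError("module_genes: duplicate symbols after normalization")
        if self.n_genes < 1 + len(module):
            raise ValidationError(
                "n_genes: must accommodate the anchor and all module genes"
            )

    @property
    def genes(self) -> tuple[str, ...]:
        """Gene universe: anchor first, then module genes, then filler tokens."""
        n_fill = self.n_genes - 1 - len(self.module_genes)
        named = (self.anchor,) + self.module_genes
        fillers = tuple(f"G{i + 1:05d}" for i in range(n_fill))
        if set(fillers) & set(named):
            raise ValidationError("module_genes: symbols collide with filler tokens")
        return named + fillers


def generate_dataset(spec: SimulationSpec, index: int) -> ExpressionDataset:
    """Generate the ``index``-th two-group dataset of the simulated panel.

    Control columns are baseline plus noise; case columns additionally carry
    ``effect_size`` on the anchor (always) and on each module gene with
    probability ``module_penetrance``. A per-dataset random subset of the
    remaining genes receives an independent shift of magnitude 1-2 log2 units
    with random sign, emulating unrelated differential expression; this
    subset is resampled for every dataset so only the planted module is
    systematically shared across the panel.
    """
    if not 0 <= index < spec.n_datasets:
        raise ValidationError(
            f"index: must lie in [0, {spec.n_datasets}) for this spec"
        )
    rng = substream(spec.seed, "dataset", index)
    genes = spec.genes
    n_genes, n = spec.n_genes, spec.n_per_group
    n_module = len(spec.module_genes)

    baseline = rng.normal(8.0, 1.5, n_genes)
    shift = np.zeros(n_genes)
    shift[0] = spec.effect_size
    carries = rng.random(n_module) < spec.module_penetrance
    shift[1:1 + n_module][carries] = spec.effect_size
    others = np.arange(1 + n_module, n_genes)
    n_bg = int(round(spec.background_de_fraction * len(others)))
    if n_bg:
        chosen = rng.choice(others, n_bg, replace=False)
        mags = rng.uniform(*_BACKGROUND_SHIFT_RANGE, n_bg)
        signs = rng.choice([-1.0, 1.0], n_bg)
        shift[chosen] = mags * signs
    noise = rng.normal(0.0, spec.noise_sd, (n_genes, 2 * n))

    values = np.empty((n_genes, 2 * n))
    values[:, :n] = baseline[:, None] + noise[:, :n]
    values[:, n:] = (baseline + shift)[:, None] + noise[:, n:]

    dataset_id = f"SIM{index + 1:03d}"
    columns = [f"ctrl_{i + 1}" for i in range(n)] + [f"case_{i + 1}" for i in range(n)]
    df = pd.DataFrame(values, index=list(genes), columns=columns)
    group_of = {c: ("control" if c.startswith("ctrl") else "case") for c in columns}
    return ExpressionDataset(dataset_id, df, group_of)


def generate_gmt(universe: Sequence[str], n_sets: int,
                 set_size_range: tuple[int, int], planted_set: Sequence[str],
                 seed: int, planted_id: str = "PLANTED") -> GeneSetCollection:
    """Random gene-set collection plus one set equal to ``planted_set``."""
    uni = sorted({normalize_symbol(g) for g in universe})
    planted = frozenset(normalize_symbol(g) for g in planted_set)
    if not planted <= set(uni):
        raise ValidationError("planted_set: must be a subset of the universe")
    if not planted:
        raise ValidationError("planted_set: must be non-empty")
    lo, hi = set_size_range
    if not (1 <= lo <= hi <= len(uni)):
        raise ValidationError("set_size_range: need 1 <= lo <= hi <= |universe|")
    if n_sets < 0:
        raise ValidationError("n_sets: must be non-negative")
    rng = substream(seed, "gmt")
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(uni, size, replace=False))
        sid = f"RS{i + 1:04d}"
        sets[sid] = members
        descriptions[sid] = "random gene set"
    sets[planted_id] = planted
    descriptions[planted_id] = "planted gene set"
    return GeneSetCollection(sets, descriptions)


def generate_reference_set(universe: Sequence[str], size: int,
                           enriched_pool: Sequence[str], excess_fraction: float,
                           seed: int) -> set[str]:
    """Reference gene set with a controlled excess of ``enriched_pool`` members.

    Exactly ``round(excess_fraction * size)`` members come from the pool; the
    remainder is drawn uniformly from the universe outside the pool, so the
    pool overlap of the result is deterministic.
    """
    uni = sorted({normalize_symbol(g) for g in universe})
    pool = sorted({normalize_symbol(g) for g in enriched_pool})
    if not set(pool) <= set(uni):
        raise ValidationError("enriched_pool: must be a subset of the universe")
    if not 0.0 <= excess_fraction <= 1.0:
        raise ValidationError("excess_fraction: must lie in [0, 1]")
    if size > len(uni):
        raise ValidationError("size: exceeds the universe")
    n_pool = round(excess_fraction * size)
    if n_pool > len(pool):
        raise ValidationError("excess_fraction: requires more pool members than exist")
    outside = sorted(set(uni) - set(pool))
    n_rest = size - n_pool
    if n_rest > len(outside):
        raise ValidationError("size: not enough non-pool genes in the universe")
    rng = substream(seed, "reference")
    picked: set[str] = set()
    if n_pool:
        picked |= set(rng.choice(pool, n_pool, replace=False))
    if n_rest:
        picked |= set(rng.choice(outside, n_rest, replace=False))
    return picked


def generate_ppi(n_nodes: int, clique_sizes: Sequence[int], p_background: float,
                 seed: int, nodes: Sequence[str] | None = None) -> InteractionGraph:
    """Undirected simple graph with planted cliques plus Erdos-Renyi background.

    The first ``sum(clique_sizes)`` nodes are partitioned into fully connected
    cliques; every remaining pair of nodes (including clique-to-clique pairs)
    is edged independently with probability ``p_background``. Pass ``nodes``
    to plant the cliques on specific protein symbols.
    """
    if nodes is None:
        node_list = [f"P{i + 1:05d}" for i in range(n_nodes)]
    else:
        node_list = [normalize_symbol(x) for x in nodes]
        if len(set(node_list)) != len(node_list):
            raise ValidationError("nodes: duplicate symbols after normalization")
        if len(node_list) != n_nodes:
            raise ValidationError("nodes: length must equal n_nodes")
    if any(c < 1 for c in clique_sizes):
        raise ValidationError("clique_sizes: sizes must be positive")
    if sum(clique_sizes) > n_nodes:
        raise ValidationError("clique_sizes: cliques exceed n_nodes")
    if not 0.0 <= p_background <= 1.0:
        raise ValidationError("p_background: must lie in [0, 1]")

    clique_of = np.full(n_nodes, -1)
    pos = 0
    for ci, size in enumerate(clique_sizes):
        clique_of[pos:pos + size] = ci
        pos += size

    g = nx.Graph()
    g.add_nodes_from(node_list)
    rng = substream(seed, "ppi")
    rand = rng.random((n_nodes, n_nodes))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            same_clique = clique_of[i] >= 0 and clique_of[i] == clique_of[j]
            if same_clique or rand[i, j] < p_background:
                g.add_edge(node_list[i], node_list[j])
    return InteractionGraph(g)
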