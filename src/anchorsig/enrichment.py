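"""Hypergeometric over-representation analysis and the multi-level consensus rule.

A query gene list is tested against every set of a collection with the
upper-tail hypergeometric test: with a universe of ``N`` genes of which ``K``
belong to the set, drawing the ``n`` query genes at random, the p-value is
``P[X >= k]`` for the observed overlap ``k``. A set is flagged significant
only when the overlap reaches a minimum number of genes (default 2) and the
p-value (or the Benjamini-Hochberg q-value when ``adjust`` is on) falls below
alpha.

The consensus rule combines the per-level analyses of the commonality slices:
a set is a consensus hit when it is significant at a minimum number of the
levels tested (default 3 of 4).

The tail probability is accumulated in log space (log-binomial terms via
``gammaln``, combined with ``logsumexp``), which stays accurate for overlaps
deep in the tail where naive summation underflows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from ._utils import normalize_symbols
from .errors import ValidationError
from .io import GeneSetCollection

DEFAULT_MIN_OVERLAP = 2
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_LEVELS = 3

#: smallest representable positive double; the tail is never reported as 0
_TINY = 5e-324


@dataclass
class EnrichmentRecord:
    """One gene set's over-representation result."""

    set_id: str
    overlap_genes: tuple[str, ...]
    k: int            # overlap size
    K: int            # set size within the universe
    n: int            # query size within the universe
    N: int            # universe size
    p_value: float    # upper-tail hypergeometric
    q_value: float | None = None   # BH-adjusted across the collection
    significant: bool = False


@dataclass(frozen=True)
class ConsensusResult:
    """Which commonality levels flagged a set, and the consensus verdict."""

    set_id: str
    levels_tested: tuple[int, ...]
    levels_significant: tuple[int, ...]
    consensus: bool


def _log_comb(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """``P[X >= k]`` for ``X ~ Hypergeometric(N, K, n)``, stable in log space."""
    k, K, n, N = int(k), int(K), int(n), int(N)
    if N < 0 or not 0 <= K <= N or not 0 <= n <= N:
        raise ValidationError("hypergeom_tail: need 0 <= K, n <= N")
    if not 0 <= k <= min(K, n):
        raise ValidationError("hypergeom_tail: need 0 <= k <= min(K, n)")
    if k == 0:
        return 1.0
    j_lo = max(k, n + K - N)
    js = np.arange(j_lo, min(K, n) + 1)
    log_terms = _log_comb(K, js) + _log_comb(N - K, n - js) - _log_comb(N, n)
    p = float(np.exp(logsumexp(log_terms)))
    return min(1.0, max(p, _TINY))


def run_ora(query: Iterable[str], coll: GeneSetCollection,
            universe: Iterable[str], min_overlap: int = DEFAULT_MIN_OVERLAP,
            alpha: float = DEFAULT_ALPHA, adjust: bool = False) -> list[EnrichmentRecord]:
    """Over-representation analysis of a query list against a collection.

    Query genes outside the universe are dropped with a warning; set members
    outside the universe are trimmed from ``K``. One record is produced per
    set with non-zero overlap, sorted by (p-value, set id). Both raw p and BH
    q are always reported; ``adjust`` only switches which one the
    significance flag uses.
    """
    uni = normalize_symbols(universe)
    if not uni:
        raise ValidationError("run_ora: empty universe")
    q = normalize_symbols(query)
    dropped = q - uni
    if dropped:
        warnings.warn(
            f"run_ora: {len(dropped)} query gene(s) outside the universe dropped"
        )
        q &= uni
    if not q:
        raise ValidationError("run_ora: query empty after restriction to universe")
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha: must lie in (0, 1)")
    if min_overlap < 1:
        raise ValidationError("min_overlap: must be at least 1")

    N, n = len(uni), len(q)
    records: list[EnrichmentRecord] = []
    for sid in sorted(coll.sets):
        members = coll.sets[sid] & uni
        K = len(members)
        overlap = q & members
        k = len(overlap)
        if k == 0:
            continue
        p = hypergeom_tail(k, K, n, N)
        records.append(EnrichmentRecord(sid, tuple(sorted(overlap)), k, K, n, N, p))
    if records:
        qvals = multipletests([r.p_value for r in records], method="fdr_bh")[1]
        for rec, qv in zip(records, qvals):
            rec.q_value = float(qv)
            crit = rec.q_value if adjust else rec.p_value
            rec.significant = rec.k >= min_overlap and crit < alpha
    records.sort(key=lambda r: (r.p_value, r.set_id))
    return records


def consensus_over_levels(per_level: Mapping[int, Iterable[EnrichmentRecord]],
                          min_levels: int = DEFAULT_MIN_LEVELS) -> list[ConsensusResult]:
    """Combine per-level ORA results into consensus verdicts.

    A set reaches consensus when it was flagged significant at at least
    ``min_levels`` of the levels tested.
    """
    if not per_level:
        raise ValidationError("consensus_over_levels: at least one level required")
    if min_levels < 1:
        raise ValidationError("min_levels: must be at least 1")
    levels = tuple(sorted(per_level))
    sig_at: dict[str, list[int]] = {}
    seen: set[str] = set()
    for lv in levels:
        for rec in per_level[lv]:
            seen.add(rec.set_id)
            if rec.significant:
                sig_at.setdefault(rec.set_id, []).append(lv)
    results = [
        ConsensusResult(
            sid, levels, tuple(sorted(sig_at.get(sid, ()))),
            len(sig_at.get(sid, ())) >= min_levels,
        )
        for sid in sorted(seen)
    ]
    results.sort(key=lambda r: (-len(r.levels_significant), r.set_id))
    return results


def compare_cohorts(up: Iterable[ConsensusResult], down: Iterable[ConsensusResult],
                    group_map: Mapping[str, str]) -> dict[str, tuple[int, int]]:
    """Tally consensus pathways per functional group for two cohorts.

    ``group_map`` is user-supplied curation mapping set ids to functional
    group labels; consensus sets without a mapping are tallied under
    ``"other"``. Returns ``group -> (n_up, n_down)``.
    """
    tally: dict[str, list[int]] = {}
    for side, results in enumerate((up, down)):
        for rec in results:
            if not rec.consensus:
                continue
            group = group_map.get(rec.set_id, "other")
            tally.setdefault(group, [0, 0])[side] += 1
    return {g: (c[0], c[1]) for g, c in sorted(tally.items())}
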