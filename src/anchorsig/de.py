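"""Per-dataset two-group differential expression and the anchor gate.

A dataset contributes a differentially expressed (DE) gene list to the
meta-analysis only when the anchor gene is itself significantly differentially
expressed in the required direction. Testing uses Welch's unequal-variance t
with Satterthwaite degrees of freedom; the raw two-sided p-value is compared
against the gate's alpha with no multiple-testing correction (an optional
Benjamini-Hochberg variant of the gene cut is available via ``adjust``).

Zero-variance conventions keep noiseless fixtures usable: identical groups
give ``t = 0, p = 1``; zero within-group variance with unequal means gives an
infinite t and ``p = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._utils import normalize_symbol
from .errors import ValidationError
from .io import ExpressionDataset


@dataclass(frozen=True)
class DEGeneRecord:
    """One gene's two-group test result."""

    gene: str
    log2fc: float      # case - control mean difference
    t_stat: float      # Welch statistic (may be +/- inf in degenerate cases)
    df: float          # Welch-Satterthwaite degrees of freedom
    p_value: float     # two-sided


@dataclass(frozen=True)
class GateConfig:
    """Anchor gate: significance threshold and required direction."""

    anchor: str
    direction: str = "up"      # 'up' or 'down'
    alpha: float = 0.05
    adjust: bool = False       # BH-adjust the gene-list cut (gate stays raw-p)

    def __post_init__(self) -> None:
        object.__setattr__(self, "anchor", normalize_symbol(self.anchor))
        if self.direction not in ("up", "down"):
            raise ValidationError("direction: must be 'up' or 'down'")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha: must lie in (0, 1)")


def _welch_arrays(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch t over the last axis. Returns (t, df, p)."""
    n1, n2 = x.shape[-1], y.shape[-1]
    m1, m2 = x.mean(axis=-1), y.mean(axis=-1)
    v1, v2 = x.var(axis=-1, ddof=1), y.var(axis=-1, ddof=1)
    diff = m1 - m2
    se2 = v1 / n1 + v2 / n2
    ok = se2 > 0

    t = np.empty_like(diff)
    df = np.full_like(diff, float(n1 + n2 - 2))
    safe = np.where(ok, se2, 1.0)
    t[...] = diff / np.sqrt(safe)
    denom = v1 ** 2 / (n1 ** 2 * (n1 - 1)) + v2 ** 2 / (n2 ** 2 * (n2 - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        df = np.where(ok, se2 ** 2 / np.where(ok, denom, 1.0), df)
    # zero-variance conventions
    degen = ~ok
    t = np.where(degen & (diff == 0), 0.0, t)
    with np.errstate(invalid="ignore"):
        t = np.where(degen & (diff != 0), np.sign(diff) * np.inf, t)
    p = np.where(
        np.isinf(t), 0.0,
        2.0 * stats.t.sf(np.abs(np.where(np.isinf(t), 0.0, t)), df),
    )
    return t, df, np.minimum(p, 1.0)


def welch_t(xs: Sequence[float], ys: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns ``(t, df, p)`` two-sided."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValidationError("welch_t expects one-dimensional samples")
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("welch_t needs at least 2 observations per group")
    t, df, p = _welch_arrays(x[None, :], y[None, :])
    return float(t[0]), float(df[0]), float(p[0])


def run_de(ds: ExpressionDataset) -> list[DEGeneRecord]:
    """Test every gene of a dataset, case versus control, in input gene order."""
    ctrl_cols, case_cols = ds.control_samples, ds.case_samples
    if len(ctrl_cols) < 2 or len(case_cols) < 2:
        raise ValidationError(
            f"dataset '{ds.dataset_id}': need at least 2 samples per group"
        )
    case = ds.values[case_cols].to_numpy()
    ctrl = ds.values[ctrl_cols].to_numpy()
    t, df, p = _welch_arrays(case, ctrl)
    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    return [
        DEGeneRecord(g, float(log2fc[i]), float(t[i]), float(df[i]), float(p[i]))
        for i, g in enumerate(ds.genes)
    ]


def gate_and_extract(records: Iterable[DEGeneRecord],
                     cfg: GateConfig) -> tuple[bool, set[str]]:
    """Apply the anchor gate and, if it passes, extract the DE gene list.

    The gate passes iff the anchor's p-value is at most ``alpha`` and the sign
    of its log2 fold change matches the required direction. When the gate
    passes, the DE list holds every gene (anchor included) at ``p <= alpha``
    regardless of direction; otherwise it is empty.
    """
    records = list(records)
    anchor_rec = next((r for r in records if r.gene == cfg.anchor), None)
    if anchor_rec is None:
        raise ValidationError(f"anchor '{cfg.anchor}' not among tested genes")
    wanted_sign = 1.0 if cfg.direction == "up" else -1.0
    passed = (
        anchor_rec.p_value <= cfg.alpha
        and np.sign(anchor_rec.log2fc) == wanted_sign
    )
    if not passed:
        return False, set()
    if cfg.adjust:
        pvals = np.array([r.p_value for r in records])
        reject = multipletests(pvals, alpha=cfg.alpha, method="fdr_bh")[0]
        de = {r.gene for r, rej in zip(records, reject) if rej}
        de.add(cfg.anchor)
    else:
        de = {r.gene for r in records if r.p_value <= cfg.alpha}
    return True, de
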