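"""Reference-set intersection with a random-same-size-set permutation null.

The combined anchor cohort is intersected with a reference gene set; the
significance of the observed intersection size is judged against draws of
random sets of the same size from the universe. The empirical p-value uses
the add-one estimator ``(1 + #{null >= observed}) / (1 + n_perm)`` so it is
never zero; a z-score against the null mean and standard deviation is
reported alongside.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._utils import normalize_symbols, substream
from .errors import ValidationError

DEFAULT_N_PERM = 10


@dataclass(frozen=True)
class OverlapTestResult:
    """Observed intersection size versus its permutation null."""

    observed: int
    n_perm: int
    null_mean: float
    null_sem: float    # sample SD / sqrt(n_perm)
    z_score: float     # (observed - mean) / SD; +/- inf when SD = 0 and obs != mean
    empirical_p: float # add-one one-sided (>= observed)


def intersect_sets(a: Iterable[str], b: Iterable[str]) -> set[str]:
    """Normalized intersection of two gene collections."""
    return normalize_symbols(a) & normalize_symbols(b)


def permutation_null(reference_size: int, universe: Iterable[str],
                     target: Iterable[str], n_perm: int = DEFAULT_N_PERM,
                     seed: int = 0) -> np.ndarray:
    """Null overlap samples: ``|random_set ∩ target|`` for uniform random sets.

    Each draw picks ``reference_size`` genes without replacement from the
    universe (draws are independent of each other) and records the overlap
    with ``target``. Target genes outside the universe are dropped with a
    warning. Fully reproducible from ``seed``.
    """
    uni = sorted(normalize_symbols(universe))
    if not uni:
        raise ValidationError("permutation_null: empty universe")
    if not 0 <= reference_size <= len(uni):
        raise ValidationError("reference_size: must lie in [0, |universe|]")
    if n_perm < 1:
        raise ValidationError("n_perm: must be positive")
    tgt = normalize_symbols(target)
    outside = tgt - set(uni)
    if outside:
        warnings.warn(
            f"permutation_null: {len(outside)} target gene(s) outside the "
            f"universe dropped"
        )
        tgt &= set(uni)
    mask = np.fromiter((g in tgt for g in uni), dtype=bool, count=len(uni))
    rng = substream(seed, "permutation_null")
    n_uni = len(uni)
    draws = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        idx = rng.choice(n_uni, reference_size, replace=False)
        draws[i] = int(mask[idx].sum())
    return draws


def evaluate(observed: int, null_samples: Sequence[int]) -> OverlapTestResult:
    """Summarize an observed overlap against its permutation null draws."""
    null = np.asarray(null_samples, dtype=float)
    if null.ndim != 1 or len(null) < 2:
        raise ValidationError("evaluate: need at least 2 null samples (SEM undefined)")
    observed = int(observed)
    n_perm = len(null)
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    sem = sd / math.sqrt(n_perm)
    if sd == 0.0:
        z = 0.0 if observed == mean else math.copysign(math.inf, observed - mean)
    else:
        z = (observed - mean) / sd
    p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return OverlapTestResult(observed, n_perm, mean, sem, float(z), float(p))


def overlap_test(cohort: Iterable[str], reference: Iterable[str],
                 universe: Iterable[str], n_perm: int = DEFAULT_N_PERM,
                 seed: int = 0) -> tuple[OverlapTestResult, set[str]]:
    """Convenience wrapper: intersect, build the null, evaluate.

    Returns the test result and the observed intersection itself. The null
    draws random sets the size of the reference (restricted to the universe)
    and counts their overlap with the cohort.
    """
    uni = normalize_symbols(universe)
    coh = normalize_symbols(cohort) & uni
    ref = normalize_symbols(reference) & uni
    inter = coh & ref
    null = permutation_null(len(ref), uni, coh, n_perm=n_perm, seed=seed)
    return evaluate(len(inter), null), inter
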