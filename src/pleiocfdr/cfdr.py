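"""Empirical conditional false discovery rate (cFDR) for two traits.

The cFDR of SNP i is the estimated probability that it is null for the
principal trait given that both its principal p-value and its
conditioning-trait p-value fall below their observed values.  The
empirical estimator used here is

    cfdr_i = p2_i * #{j : p1_j <= p1_i} / #{j : p1_j <= p1_i and
                                              p2_j <= p2_i},

clipped to (0, 1]: the principal p-value divided by the conditional
empirical CDF of p2 given the conditioning stratum.  Counting is
inclusive at both coordinates and the denominator always contains SNP i
itself, so it is never 0.  With a degenerate conditioning vector the
estimator reduces exactly to the unconditional empirical FDR
p2_i * m / rank(p2_i).

Dominance counting is O(m log m) via a Fenwick tree (numba-compiled when
available), so genome-wide panels (~750k SNPs) run in well under a
second.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _dominance_counts_kernel(p1_sorted_vals: np.ndarray,
                             p2_ranks_sorted: np.ndarray,
                             n_p2_ranks: int) -> np.ndarray:
    """For points sorted by p1 ascending, count for each point the number
    of points j with p1_j <= p1_i and p2_j <= p2_i (both inclusive).

    Ties in p1 are handled by inserting each full tie-group into the
    Fenwick tree before querying any of its members.
    """
    m = len(p1_sorted_vals)
    tree = np.zeros(n_p2_ranks + 1, dtype=np.int64)
    out = np.zeros(m, dtype=np.int64)
    i = 0
    while i < m:
        j = i
        while j < m and p1_sorted_vals[j] == p1_sorted_vals[i]:
            j += 1
        for k in range(i, j):           # insert the whole p1 tie-group
            idx = p2_ranks_sorted[k]
            while idx <= n_p2_ranks:
                tree[idx] += 1
                idx += idx & (-idx)
        for k in range(i, j):           # then query each member
            idx = p2_ranks_sorted[k]
            c = 0
            while idx > 0:
                c += tree[idx]
                idx -= idx & (-idx)
            out[k] = c
        i = j
    return out


def _dominance_counts(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """#{j : p1_j <= p1_i and p2_j <= p2_i} for every i."""
    order = np.argsort(p1, kind="stable")
    uniq2 = np.unique(p2)
    ranks2 = (np.searchsorted(uniq2, p2) + 1).astype(np.int64)
    counts_sorted = _dominance_counts_kernel(
        p1[order], ranks2[order], len(uniq2))
    out = np.empty(len(p1), dtype=np.int64)
    out[order] = counts_sorted
    return out


@dataclass
class CFDRResult:
    """Per-SNP cFDR estimates for one principal trait.

    ``table`` columns: id, p1 (conditioning), p2 (principal), cfdr,
    trait2, significant (cfdr < alpha, strict).
    """

    table: pd.DataFrame
    trait2: str
    alpha: float

    @property
    def cfdr(self) -> np.ndarray:
        return self.table["cfdr"].to_numpy()

    @property
    def significant(self) -> np.ndarray:
        return self.table["significant"].to_numpy()


def _validate_p(name: str, p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if not ((p > 0) & (p <= 1)).all():
        raise ValueError(f"{name} must lie in (0, 1] (p = 0 is rejected, "
                         "not floored)")
    return p


def empirical_cfdr(p2: np.ndarray, p1: np.ndarray,
                   ids: Optional[Sequence[str]] = None,
                   trait2: str = "trait2",
                   alpha: float = 0.05,
                   monotone_envelope: bool = False) -> CFDRResult:
    """Empirical cFDR of the principal trait (p2) given the conditioning
    trait (p1); see the module docstring for the estimator.

    ``monotone_envelope`` (off by default) replaces each estimate with
    the minimum raw estimate over all SNPs with p2 at least as large,
    which makes the result monotone non-decreasing in p2; the raw
    estimator can violate that ordering in sparse tails.
    """
    p2 = _validate_p("p2", p2)
    p1 = _validate_p("p1", p1)
    if len(p1) != len(p2):
        raise ValueError("p1 and p2 length mismatch")
    m = len(p1)
    order1 = np.sort(p1)
    numer = np.searchsorted(order1, p1, side="right")
    denom = _dominance_counts(p1, p2)
    cfdr = np.minimum(p2 * numer / denom, 1.0)
    if monotone_envelope:
        order = np.argsort(p2, kind="stable")[::-1]  # p2 descending
        env = np.minimum.accumulate(cfdr[order])
        out = np.empty_like(cfdr)
        out[order] = env
        # equal p2 must share the envelope value (take the group minimum)
        df = pd.Series(out).groupby(p2).transform("min")
        cfdr = df.to_numpy()
    if ids is None:
        ids = [f"snp{i:07d}" for i in range(m)]
    table = pd.DataFrame({"id": list(ids), "p1": p1, "p2": p2,
                          "cfdr": cfdr, "trait2": trait2,
                          "significant": cfdr < alpha})
    return CFDRResult(table=table, trait2=trait2, alpha=alpha)


def empirical_fdr(p: np.ndarray) -> np.ndarray:
    """Unconditional empirical FDR p_i * m / rank(p_i), inclusive ranks,
    clipped to (0, 1]; the degenerate-conditioning limit of the cFDR."""
    p = _validate_p("p", p)
    m = len(p)
    rank = np.searchsorted(np.sort(p), p, side="right")
    return np.minimum(p * m / rank, 1.0)


def call_significant(result: CFDRResult,
                     alpha: float = 0.05) -> np.ndarray:
    """Discovery mask at cFDR < alpha (strict inequality: a SNP at
    exactly alpha is not called)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return result.cfdr < alpha


@dataclass
class CombinedCFDR:
    """Per-SNP minimum cFDR across trait-2 phenotypes.

    ``summary`` has one row per SNP (id, min_cfdr, best_trait,
    significant); ``per_trait`` retains every per-trait row for
    reporting.
    """

    summary: pd.DataFrame
    per_trait: pd.DataFrame
    alpha: float


def combine_traits(results: Iterable[CFDRResult],
                   alpha: float = 0.05) -> CombinedCFDR:
    """Combine per-trait cFDR results: a SNP's score is its minimum cFDR
    over the trait-2 phenotypes, with all per-trait rows retained."""
    results = list(results)
    if not results:
        raise ValueError("no results to combine")
    base_ids = results[0].table["id"].to_numpy()
    for r in results[1:]:
        if not np.array_equal(r.table["id"].to_numpy(), base_ids):
            raise ValueError("SNP sets are misaligned across traits")
    per_trait = pd.concat([r.table for r in results], ignore_index=True)
    cfdr_mat = np.column_stack([r.cfdr for r in results])
    best = np.argmin(cfdr_mat, axis=1)
    min_cfdr = cfdr_mat[np.arange(len(base_ids)), best]
    traits = np.array([r.trait2 for r in results])
    summary = pd.DataFrame({"id": base_ids, "min_cfdr": min_cfdr,
                            "best_trait": traits[best],
                            "significant": min_cfdr < alpha})
    return CombinedCFDR(summary=summary, per_trait=per_trait, alpha=alpha)
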