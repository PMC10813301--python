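"""Conditional (stratified) Q-Q curves for cross-trait enrichment.

A conditional Q-Q plot draws, for each conditioning stratum
{i : p_cond,i <= t} at increasingly strict thresholds t, the observed
-log10 principal-trait p-values against the expected uniform quantiles of
the stratum.  Shared genetic signal shows up as an earlier and greater
departure from the diagonal (a leftward/upward shift) in the stricter
strata; the deflection statistic scalarizes that shift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

DEFAULT_STRATA = (1.0, 0.1, 0.01, 0.001)


@dataclass
class StratumCurve:
    """One Q-Q curve: points ordered by increasing expected quantile."""

    threshold: float
    expected: np.ndarray   # -log10 uniform quantile r/(s+1), ascending
    observed: np.ndarray   # -log10 p, non-decreasing
    n_snps: int
    deflection: float


@dataclass
class QQCurves:
    """Conditional Q-Q curves at nested conditioning strata."""

    strata: List[StratumCurve]

    @property
    def thresholds(self) -> Tuple[float, ...]:
        return tuple(c.threshold for c in self.strata)

    @property
    def deflections(self) -> Tuple[float, ...]:
        return tuple(c.deflection for c in self.strata)


def _curve_points(p_sub: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Expected/observed -log10 arrays for one stratum, expected
    ascending.  The expected quantile of the r-th smallest p among s is
    r/(s+1), the mean of the r-th uniform order statistic."""
    s = len(p_sub)
    p_sorted = np.sort(p_sub)                       # ascending
    ranks = np.arange(1, s + 1)
    expected = -np.log10(ranks / (s + 1.0))         # descending in rank
    observed = -np.log10(p_sorted)
    return expected[::-1], observed[::-1]


def deflection_statistic(expected: np.ndarray,
                         observed: np.ndarray) -> float:
    """Mean excess of observed over expected -log10 p across the curve's
    upper decile of expected quantiles, floored at 0.

    Zero for a curve on the diagonal; a constant +1 offset in -log10
    units gives exactly 1.
    """
    if len(expected) == 0:
        raise ValueError("curve is empty")
    k = max(1, int(np.ceil(0.1 * len(expected))))
    top = np.argsort(expected)[-k:]
    return float(max(np.mean(observed[top] - expected[top]), 0.0))


def conditional_qq(p_principal: np.ndarray, p_cond: np.ndarray,
                   strata_thresholds: Sequence[float] = DEFAULT_STRATA,
                   ) -> QQCurves:
    """Stratified Q-Q curves of principal-trait p-values given
    conditioning-trait association strength.

    Strata are nested subsets {i : p_cond,i <= t}; the first threshold
    (1.0 by convention) recovers the unconditional Q-Q curve.
    """
    p1 = np.asarray(p_principal, dtype=float)
    pc = np.asarray(p_cond, dtype=float)
    if len(p1) != len(pc):
        raise ValueError("p_principal and p_cond length mismatch")
    if len(p1) < 10:
        raise ValueError("need at least 10 SNPs")
    for name, v in (("p_principal", p1), ("p_cond", pc)):
        if not ((v > 0) & (v <= 1)).all():
            raise ValueError(f"{name} must lie in (0, 1]")
    thresholds = tuple(strata_thresholds)
    if any(a <= b for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("strata thresholds must be strictly decreasing")
    strata = []
    for t in thresholds:
        sel = pc <= t
        s = int(sel.sum())
        if s == 0:
            strata.append(StratumCurve(t, np.empty(0), np.empty(0), 0,
                                       0.0))
            continue
        expected, observed = _curve_points(p1[sel])
        d = deflection_statistic(expected, observed)
        strata.append(StratumCurve(t, expected, observed, s, d))
    return QQCurves(strata=strata)


def null_band_epsilon(n: int, alpha: float = 0.05) -> float:
    """Half-width of the Dvoretzky–Kiefer–Wolfowitz simultaneous
    confidence band for an empirical CDF of n uniform draws."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(np.sqrt(np.log(2.0 / alpha) / (2.0 * n)))


def curve_within_null_band(curve: StratumCurve,
                           alpha: float = 0.05) -> bool:
    """Whether a stratum curve stays inside the DKW band of the diagonal.

    The check is on the p-value scale: for the r-th smallest p among s,
    |r/s - p_(r)| <= eps(s, alpha) for every r.
    """
    s = curve.n_snps
    if s == 0:
        return True
    eps = null_band_epsilon(s, alpha)
    p_sorted = np.sort(10.0 ** (-curve.observed))   # ascending p
    ecdf = np.arange(1, s + 1) / s
    return bool(np.max(np.abs(ecdf - p_sorted)) <= eps)
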