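"""LD-based clumping of significant SNPs into independent loci.

Greedy best-first clumping: repeatedly take the unassigned SNP with the
smallest score (minimum cFDR) as an index variant and assign to it every
unassigned same-chromosome SNP strictly less than the window away and
with r² strictly above the threshold against the index.  The number of
clumps estimates the number of independent loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .synthdata import MISSING, GenotypeMatrix

DEFAULT_WINDOW_BP = 500_000
DEFAULT_R2_MIN = 0.1


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors on
    pairwise-complete samples.

    Returns NaN (undefined) if either vector is monomorphic on the
    complete cases; clumping treats undefined LD as r² = 0.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if len(g1) != len(g2):
        raise ValueError("dosage vectors must have equal length")
    ok = (g1 != MISSING) & (g2 != MISSING) & np.isfinite(g1) & \
        np.isfinite(g2)
    a, b = g1[ok], g2[ok]
    if len(a) < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


class LDSource:
    """Interface for pairwise LD lookups keyed by SNP id."""

    def r2(self, id_a: str, id_b: str) -> float:  # pragma: no cover
        raise NotImplementedError


class GenotypeLD(LDSource):
    """LD computed on the fly from a genotype panel (the reference panel
    is the analyzed half in full-pipeline runs)."""

    def __init__(self, G: GenotypeMatrix):
        self._dos = G.dosages
        self._col = {s: i for i, s in enumerate(G.snp_meta["id"])}

    def r2(self, id_a: str, id_b: str) -> float:
        try:
            ia, ib = self._col[id_a], self._col[id_b]
        except KeyError as e:
            raise KeyError(f"no genotypes for SNP pair ({id_a}, {id_b})"
                           ) from e
        if ia == ib:
            return 1.0
        return ld_r2(self._dos[:, ia], self._dos[:, ib])


class PrecomputedLD(LDSource):
    """LD from a precomputed symmetric pairwise table (summary-stat-only
    runs).  Missing pairs raise, naming the pair."""

    def __init__(self, table: pd.DataFrame):
        need = {"snp_a", "snp_b", "r2"}
        cols = {c.lower(): c for c in table.columns}
        if not need <= set(cols):
            raise ValueError(f"LD table must have columns {sorted(need)}")
        self._r2: Dict[Tuple[str, str], float] = {}
        for a, b, r in zip(table[cols["snp_a"]], table[cols["snp_b"]],
                           table[cols["r2"]]):
            self._r2[(str(a), str(b))] = float(r)
            self._r2[(str(b), str(a))] = float(r)

    def r2(self, id_a: str, id_b: str) -> float:
        if id_a == id_b:
            return 1.0
        try:
            return self._r2[(id_a, id_b)]
        except KeyError as e:
            raise KeyError(f"no LD entry for SNP pair ({id_a}, {id_b})"
                           ) from e


@dataclass
class Clump:
    """One independent locus: the index variant and its members (the
    index is always its own first member)."""

    index_id: str
    chrom: str
    index_pos: int
    index_score: float
    member_ids: List[str] = field(default_factory=list)


def greedy_clump(snps: pd.DataFrame, ld_source: LDSource,
                 window_bp: int = DEFAULT_WINDOW_BP,
                 r2_min: float = DEFAULT_R2_MIN) -> List[Clump]:
    """Greedy best-first clumping of a significant SNP set.

    ``snps`` needs columns id, chrom, pos, score (smaller = better, e.g.
    minimum cFDR).  Assignment is one-pass — a SNP joins the first index
    that claims it — with strict boundaries: |pos - index pos| <
    ``window_bp`` and r² > ``r2_min``.  Index order is ascending score,
    ties broken by (chrom, pos, id).  Undefined (NaN) r² counts as 0.
    """
    for c in ("id", "chrom", "pos", "score"):
        if c not in snps.columns:
            raise ValueError(f"snps frame lacks required column {c!r}")
    if snps["score"].isna().any():
        raise ValueError("scores must be available for all SNPs")
    df = snps.reset_index(drop=True)
    order = df.sort_values(
        ["score", "chrom", "pos", "id"], kind="mergesort").index.to_numpy()
    assigned = np.zeros(len(df), dtype=bool)
    chrom = df["chrom"].astype(str).to_numpy()
    pos = df["pos"].to_numpy(dtype=np.int64)
    ids = df["id"].astype(str).to_numpy()
    score = df["score"].to_numpy(dtype=float)
    clumps: List[Clump] = []
    for i in order:
        if assigned[i]:
            continue
        assigned[i] = True
        clump = Clump(index_id=ids[i], chrom=chrom[i],
                      index_pos=int(pos[i]), index_score=float(score[i]),
                      member_ids=[ids[i]])
        near = np.flatnonzero(~assigned & (chrom == chrom[i])
                              & (np.abs(pos - pos[i]) < window_bp))
        for j in near:
            r2 = ld_source.r2(ids[i], ids[j])
            if not np.isnan(r2) and r2 > r2_min:
                assigned[j] = True
                clump.member_ids.append(ids[j])
        clumps.append(clump)
    return clumps


def build_loci_table(clumps: Iterable[Clump],
                     per_trait: pd.DataFrame,
                     annotations: Optional[Mapping[str, str]] = None,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Loci report: one row per (index SNP, significant trait-2
    phenotype), grouped by index SNP.

    ``per_trait`` is the combined per-trait cFDR frame (columns id, p1,
    p2, trait2, cfdr).  ``annotations`` optionally maps SNP id to a gene
    label.  Rows are emitted only for traits with cfdr < alpha at the
    index.
    """
    annotations = annotations or {}
    rows = []
    for clump in clumps:
        sub = per_trait[per_trait["id"] == clump.index_id]
        if sub.empty:
            raise ValueError(f"clump index {clump.index_id} absent from "
                             "cFDR results")
        sub = sub[sub["cfdr"] < alpha].sort_values("cfdr")
        for _, r in sub.iterrows():
            rows.append({"chrom": clump.chrom, "rsid": clump.index_id,
                         "pos": clump.index_pos,
                         "gene": annotations.get(clump.index_id, ""),
                         "p1": r["p1"], "trait2": r["trait2"],
                         "p2": r["p2"], "cfdr": r["cfdr"]})
    return pd.DataFrame(
        rows, columns=["chrom", "rsid", "pos", "gene", "p1", "trait2",
                       "p2", "cfdr"])
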