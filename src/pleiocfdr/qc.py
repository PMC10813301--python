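"""Sample- and SNP-level quality control and the random cohort split.

Filtering conventions (all configurable through
:class:`pleiocfdr.config.QCThresholds`): samples with a genotype missing
rate >= 2% or any missing analysis phenotype are excluded; SNPs with a
missing rate >= 2%, MAF < 0.01 or HWE exact-test p < 1e-6 are excluded.
Sample filters are applied first and SNP statistics are then recomputed on
the retained samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .config import QCThresholds
from .synthdata import MISSING, GenotypeMatrix

ANALYSIS_COLUMNS = ("aam", "t2dm", "bfp", "fbg", "hba1c",
                    "age", "bmi", "education")

# relative tolerance when comparing configuration probabilities in the
# two-sided exact test (standard guard against float round-off ties)
_HWE_REL_TOL = 1e-12


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Two-sided Hardy–Weinberg exact test p-value.

    Conditions on the observed allele counts and sums, over every
    heterozygote count attainable with those allele counts, the
    probabilities no larger than that of the observed genotype
    configuration.  Log-weights are normalized by a max-shift before
    exponentiation, so the test is stable at biobank-scale counts.

    Parameters are genotype counts (major homozygote, heterozygote, minor
    homozygote); the result is symmetric under swapping the homozygote
    labels.  Returns a p-value in (0, 1].
    """
    counts = (n_hom_major, n_het, n_hom_minor)
    for c in counts:
        if c < 0 or c != int(c):
            raise ValueError(f"genotype counts must be nonnegative "
                             f"integers, got {counts}")
    n = int(n_hom_major + n_het + n_hom_minor)
    if n == 0:
        raise ValueError("at least one genotype required")
    n_a = 2 * int(n_hom_minor) + int(n_het)
    n_b = 2 * int(n_hom_major) + int(n_het)
    n_rare = min(n_a, n_b)
    if n_rare == 0:
        return 1.0  # monomorphic: single attainable configuration

    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hom_rare - hets
    # unnormalized log conditional probability of each heterozygote count
    logw = (hets * np.log(2.0) - gammaln(hom_rare + 1.0)
            - gammaln(hets + 1.0) - gammaln(hom_common + 1.0))
    w = np.exp(logw - logw.max())
    probs = w / w.sum()
    obs_idx = (int(n_het) - (n_rare % 2)) // 2
    p = float(probs[probs <= probs[obs_idx] * (1.0 + _HWE_REL_TOL)].sum())
    return min(p, 1.0)


def hwe_exact_pvalues(n_hom_major: np.ndarray, n_het: np.ndarray,
                      n_hom_minor: np.ndarray) -> np.ndarray:
    """Vector version of :func:`hwe_exact_test` (one SNP per entry)."""
    out = np.empty(len(n_het))
    for i in range(len(n_het)):
        out[i] = hwe_exact_test(int(n_hom_major[i]), int(n_het[i]),
                                int(n_hom_minor[i]))
    return out


@dataclass
class QCReport:
    """Outcome of one QC pass.

    ``mask`` marks retained units (True = keep); ``stats`` holds the
    per-unit metrics the decision used; ``removed`` counts, per criterion,
    how many units failed it (a unit failing several criteria is counted
    under each).
    """

    kind: str  # "snp" or "sample"
    mask: np.ndarray
    stats: pd.DataFrame
    removed: Dict[str, int] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return int((~self.mask).sum())


def snp_qc(G: GenotypeMatrix, thresholds: Optional[QCThresholds] = None,
           sample_mask: Optional[np.ndarray] = None) -> QCReport:
    """Per-SNP missingness / MAF / HWE filter.

    A SNP is retained iff missing rate < ``snp_missing_max`` AND
    MAF >= ``maf_min`` AND HWE exact p >= ``hwe_p_min``, with all
    statistics computed on the (optionally pre-filtered) samples.
    """
    thresholds = thresholds or QCThresholds()
    if G.n_snps == 0 or G.n_samples == 0:
        raise ValueError("genotype matrix must be nonempty")
    d = G.dosages if sample_mask is None else G.dosages[sample_mask]
    if d.shape[0] == 0:
        raise ValueError("no samples retained before SNP QC")

    is_missing = d == MISSING
    miss_rate = is_missing.mean(axis=0)
    n_called = (~is_missing).sum(axis=0)
    n0 = ((d == 0).sum(axis=0)).astype(np.int64)
    n1 = ((d == 1).sum(axis=0)).astype(np.int64)
    n2 = ((d == 2).sum(axis=0)).astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, (n1 + 2 * n2) / (2 * n_called), 0.0)
    maf = np.minimum(freq, 1.0 - freq)
    hwe_p = np.ones(G.n_snps)
    called = n_called > 0
    hwe_p[called] = hwe_exact_pvalues(n0[called], n1[called], n2[called])

    fail_miss = miss_rate >= thresholds.snp_missing_max
    fail_maf = maf < thresholds.maf_min
    fail_hwe = hwe_p < thresholds.hwe_p_min
    mask = ~(fail_miss | fail_maf | fail_hwe)
    stats_df = pd.DataFrame({"id": G.snp_meta["id"].to_numpy(),
                             "missing_rate": miss_rate, "maf": maf,
                             "hwe_p": hwe_p})
    removed = {"missing_rate": int(fail_miss.sum()),
               "maf": int(fail_maf.sum()), "hwe": int(fail_hwe.sum())}
    return QCReport("snp", mask, stats_df, removed)


def sample_qc(G: GenotypeMatrix, phenos: pd.DataFrame,
              thresholds: Optional[QCThresholds] = None,
              pheno_columns: Optional[Sequence[str]] = None) -> QCReport:
    """Per-sample missingness filter.

    Excludes samples with genotype missing rate >= ``sample_missing_max``
    or any missing value among the analysis phenotypes/covariates.
    """
    thresholds = thresholds or QCThresholds()
    if list(phenos.index) != list(G.sample_ids):
        raise ValueError("phenotype table index does not match genotype "
                         "sample_ids")
    cols = list(pheno_columns) if pheno_columns is not None else \
        [c for c in ANALYSIS_COLUMNS if c in phenos.columns]
    miss_rate = (G.dosages == MISSING).mean(axis=1)
    pheno_ok = phenos[cols].notna().all(axis=1).to_numpy()
    fail_geno = miss_rate >= thresholds.sample_missing_max
    fail_pheno = ~pheno_ok
    mask = ~(fail_geno | fail_pheno)
    stats_df = pd.DataFrame({"sample_id": list(G.sample_ids),
                             "missing_rate": miss_rate,
                             "pheno_complete": pheno_ok})
    removed = {"missing_rate": int(fail_geno.sum()),
               "phenotype": int(fail_pheno.sum())}
    return QCReport("sample", mask, stats_df, removed)


def split_cohort(sample_ids: Sequence[str],
                 seed: int) -> Tuple[List[str], List[str]]:
    """Random split into two disjoint halves (sizes differ by at most 1).

    The split is a seeded permutation, so the same seed always reproduces
    the same partition.
    """
    ids = list(sample_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 samples to split")
    perm = np.random.default_rng(seed).permutation(len(ids))
    cut = len(ids) - len(ids) // 2
    first = [ids[i] for i in sorted(perm[:cut])]
    second = [ids[i] for i in sorted(perm[cut:])]
    return first, second


def balance_check(phenos1: pd.DataFrame, phenos2: pd.DataFrame,
                  covariates: Sequence[str],
                  categorical: Sequence[str] = ("education", "t2dm"),
                  ) -> pd.DataFrame:
    """Between-half covariate balance tests.

    Continuous covariates get a two-sample Welch t-test, categorical ones
    a chi-square test on the contingency table.  Returns one row per
    covariate with the statistic and two-sided p-value.
    """
    if len(phenos1) == 0 or len(phenos2) == 0:
        raise ValueError("both halves must be nonempty")
    rows = []
    for cov in covariates:
        if cov not in phenos1.columns or cov not in phenos2.columns:
            raise ValueError(f"covariate {cov!r} absent from phenotype "
                             "table")
        a = phenos1[cov].dropna()
        b = phenos2[cov].dropna()
        if cov in categorical:
            levels = sorted(set(a.unique()) | set(b.unique()))
            tab = np.array([[int((a == lv).sum()) for lv in levels],
                            [int((b == lv).sum()) for lv in levels]])
            tab = tab[:, tab.sum(axis=0) > 0]
            if tab.shape[1] < 2:
                stat, p = 0.0, 1.0
            else:
                stat, p, _, _ = stats.chi2_contingency(tab,
                                                       correction=False)
            test = "chi2"
        else:
            stat, p = stats.ttest_ind(a, b, equal_var=False)
            test = "t"
        rows.append({"covariate": cov, "test": test,
                     "statistic": float(stat), "p": float(p)})
    return pd.DataFrame(rows)
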