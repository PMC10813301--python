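"""Configuration objects shared across the pipeline.

Every tunable of the synthetic cohort generator, the QC stage and the
end-to-end driver lives in a frozen dataclass here, so that a run is fully
described by (config, seed) and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Tuple


class ConfigurationError(ValueError):
    """Raised when a configuration field is outside its documented range."""


def _require(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise ConfigurationError(f"{field_name}: {message}")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic two-trait biobank cohort.

    The generator emulates a female biobank cohort genotyped on a dense
    array: SNPs sit in mutually independent LD blocks with first-order
    autoregressive haplotype correlation ``block_ld_rho`` between adjacent
    sites, two phenotype axes (a quantitative age-at-menarche-like trait and
    a metabolic trait-2 axis realised as BFP / FBG / HbA1c plus a binary
    diabetes status), and a tunable fraction of causal variants shared
    between the two axes.

    Parameters
    ----------
    n_samples, n_snps, n_blocks
        Cohort and panel size.  ``n_snps`` need not divide ``n_blocks``
        evenly; the remainder is absorbed into the last block.
    block_ld_rho
        Latent-Gaussian AR(1) correlation between adjacent SNPs within a
        block, in [0, 1).  0 gives independent SNPs.
    maf_range
        Minor-allele frequencies are drawn uniformly from this interval,
        bounds in (0, 0.5].
    pi_shared, pi_trait1_only, pi_trait2_only
        Fractions of SNPs causal for both traits / trait 1 only / trait 2
        only.  The three sets are disjoint and the fractions must sum to
        at most 1.
    h2_trait1, h2_trait2
        Narrow-sense heritabilities of the two trait axes, in [0, 1].
    prevalence
        Population prevalence of the binary disease, realised by a
        liability-threshold model (default 0.0457).
    aam_mean, aam_sd
        Mean and SD (years) of the age-at-menarche trait (defaults 13.3
        and 1.5).
    ncp_trait1, ncp_trait2
        Noncentrality (mean |z|) of causal SNPs in the summary-statistic
        fast path (:func:`pleiocfdr.synthdata.simulate_summary_stats`).
    missing_rate
        Per-genotype missingness rate (for exercising QC).
    two_subpop, subpop_maf_shift
        Optional two-subpopulation structure: the second half of the
        samples draws each SNP's allele frequency shifted by a random
        ±``subpop_maf_shift`` (for exercising the PCA covariates).
    seed
        Base seed; all generator stages derive their streams from it.
    """

    n_samples: int = 6_000
    n_snps: int = 20_000
    n_blocks: int = 1_000
    block_ld_rho: float = 0.8
    maf_range: Tuple[float, float] = (0.01, 0.5)
    pi_shared: float = 0.01
    pi_trait1_only: float = 0.005
    pi_trait2_only: float = 0.005
    h2_trait1: float = 0.5
    h2_trait2: float = 0.5
    prevalence: float = 0.0457
    aam_mean: float = 13.3
    aam_sd: float = 1.5
    ncp_trait1: float = 4.0
    ncp_trait2: float = 4.0
    missing_rate: float = 0.0
    two_subpop: bool = False
    subpop_maf_shift: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_samples >= 1, "n_samples", "must be >= 1")
        _require(self.n_snps >= 1, "n_snps", "must be >= 1")
        _require(1 <= self.n_blocks <= self.n_snps, "n_blocks",
                 "must be in [1, n_snps]")
        _require(0.0 <= self.block_ld_rho < 1.0, "block_ld_rho",
                 "must be in [0, 1)")
        lo, hi = self.maf_range
        _require(0.0 < lo <= hi <= 0.5, "maf_range",
                 "bounds must satisfy 0 < lo <= hi <= 0.5")
        for name in ("pi_shared", "pi_trait1_only", "pi_trait2_only"):
            _require(0.0 <= getattr(self, name) <= 1.0, name,
                     "must be in [0, 1]")
        _require(self.pi_shared + self.pi_trait1_only + self.pi_trait2_only
                 <= 1.0, "pi_shared",
                 "causal fractions must sum to at most 1")
        for name in ("h2_trait1", "h2_trait2"):
            _require(0.0 <= getattr(self, name) <= 1.0, name,
                     "must be in [0, 1]")
        _require(0.0 < self.prevalence < 1.0, "prevalence",
                 "must be strictly inside (0, 1)")
        _require(self.aam_sd > 0, "aam_sd", "must be positive")
        _require(0.0 <= self.missing_rate < 1.0, "missing_rate",
                 "must be in [0, 1)")
        _require(0.0 <= self.subpop_maf_shift <= 0.4, "subpop_maf_shift",
                 "must be in [0, 0.4]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class QCThresholds:
    """SNP- and sample-level QC cutoffs.

    Exclusion conventions: missingness is excluded at >= the threshold,
    MAF at < ``maf_min``, HWE at exact-test p < ``hwe_p_min``.
    """

    snp_missing_max: float = 0.02
    sample_missing_max: float = 0.02
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("snp_missing_max", "sample_missing_max",
                     "maf_min", "hwe_p_min"):
            _require(0.0 < getattr(self, name) < 1.0, name,
                     "must be strictly inside (0, 1)")


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end driver configuration.

    When ``genotype_path`` is None the cohort is simulated from
    ``simulation``; otherwise genotypes (VCF or dosage TSV) and phenotypes
    (TSV) are read from disk.
    """

    out_dir: str = "pleiocfdr_run"
    genotype_path: Optional[str] = None
    phenotype_path: Optional[str] = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    pca_k: int = 10
    pca_snp_step: int = 10
    strata_thresholds: Sequence[float] = (1.0, 0.1, 0.01, 0.001)
    alpha: float = 0.05
    clump_window_bp: int = 500_000
    clump_r2_min: float = 0.1
    trait2_names: Sequence[str] = ("t2dm", "bfp", "fbg", "hba1c")
    annotation_path: Optional[str] = None
    make_figures: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        _require(0.0 < self.alpha < 1.0, "alpha", "must be in (0, 1)")
        _require(self.pca_k >= 1, "pca_k", "must be >= 1")
        _require(self.pca_snp_step >= 1, "pca_snp_step", "must be >= 1")
        _require(self.clump_window_bp > 0, "clump_window_bp",
                 "must be positive")
        _require(0.0 <= self.clump_r2_min <= 1.0, "clump_r2_min",
                 "must be in [0, 1]")
        thr = tuple(self.strata_thresholds)
        _require(len(thr) >= 1 and all(0 < t <= 1 for t in thr),
                 "strata_thresholds", "must be probabilities in (0, 1]")
        _require(all(a > b for a, b in zip(thr, thr[1:])),
                 "strata_thresholds", "must be strictly decreasing")
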