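"""Quality control and the split-sample design.

Applies the sample filter (genotype missingness >= 2% or any missing
phenotype), recomputes SNP statistics on the retained samples (missing
rate >= 2%, MAF < 0.01, HWE exact p < 1e-6), then splits the cohort into
two disjoint halves and verifies they are balanced on covariates —
the same funnel a biobank GWAS applies before association testing.
"""

import numpy as np

from pleiocfdr import (QCThresholds, SimulationConfig, balance_check,
                       sample_qc, simulate_genotypes,
                       simulate_phenotypes, snp_qc, split_cohort)

cfg = SimulationConfig(n_samples=4_000, n_snps=1_000, n_blocks=100,
                       missing_rate=0.01, seed=11)
G = simulate_genotypes(cfg)
phenos = simulate_phenotypes(G, cfg).data
phenos.iloc[:5, 0] = np.nan  # a few samples with missing phenotypes

thr = QCThresholds()
s_rep = sample_qc(G, phenos, thr)
G = G.subset(sample_mask=s_rep.mask)
phenos = phenos.loc[s_rep.mask]
print(f"sample QC removed {s_rep.n_removed} "
      f"(per criterion: {s_rep.removed})")

v_rep = snp_qc(G, thr)
G = G.subset(snp_mask=v_rep.mask)
print(f"SNP QC removed {v_rep.n_removed} "
      f"(per criterion: {v_rep.removed}); {G.n_snps} SNPs retained")

ids1, ids2 = split_cohort(G.sample_ids, seed=11)
print(f"split: {len(ids1)} + {len(ids2)} samples (disjoint halves)")

in1 = np.isin(G.sample_ids, ids1)
bal = balance_check(phenos.loc[in1], phenos.loc[~in1],
                    ["age", "bmi", "bfp", "education"])
print("between-half balance (large p = halves comparable):")
print(bal.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
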