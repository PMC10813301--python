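"""Empirical cFDR versus unconditional empirical FDR.

With shared causal SNPs, conditioning the principal trait's p-values on
the second trait's association strength re-ranks the SNPs and discovers
more of the truly shared variants at the same 0.05 cutoff.  The truth
labels come from the generator's component assignment.
"""

import numpy as np

from pleiocfdr import (SimulationConfig, empirical_cfdr, empirical_fdr,
                       simulate_summary_stats)

cfg = SimulationConfig(n_snps=100_000, pi_shared=0.01,
                       pi_trait1_only=0.0, pi_trait2_only=0.0,
                       ncp_trait1=5.0, ncp_trait2=5.0, seed=5)
pair = simulate_summary_stats(cfg)
p2 = pair.trait2["p"].to_numpy()
p1 = pair.trait1["p"].to_numpy()
shared = pair.component == "shared"

res = empirical_cfdr(p2, p1, alpha=0.05)
ufdr = empirical_fdr(p2)

cond_calls = res.significant
uncond_calls = ufdr < 0.05
print(f"{shared.sum()} truly shared SNPs among {len(p2)}")
for name, calls in [("unconditional FDR < 0.05", uncond_calls),
                    ("conditional  FDR < 0.05", cond_calls)]:
    tp = int(np.sum(calls & shared))
    fp = int(np.sum(calls & ~shared))
    fdp = fp / max(calls.sum(), 1)
    print(f"  {name}: {int(calls.sum())} calls, {tp} true, "
          f"observed FDP {fdp:.3f}")
print("conditioning buys extra true discoveries; note the uncorrected "
      "empirical estimator runs above its nominal level when the "
      "conditioning trait is informative (it is calibrated when the "
      "two traits are independent)")
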