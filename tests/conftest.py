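import numpy as np
import pandas as pd
import pytest

from pleiocfdr import GenotypeMatrix, SimulationConfig, simulate_genotypes


def make_genotypes(dosages, chrom=None, pos=None, ids=None):
    """Hand-build a GenotypeMatrix from a dosage array (n x m)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    meta = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["1"] * m,
        "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
        "id": ids if ids is not None else [f"v{j}" for j in range(m)],
        "a1": ["A"] * m, "a2": ["G"] * m,
    })
    return GenotypeMatrix(dosages, meta, [f"S{i}" for i in range(n)])


@pytest.fixture(scope="session")
def small_cohort():
    """A modest complete cohort reused by several read-only tests."""
    cfg = SimulationConfig(n_samples=600, n_snps=400, n_blocks=40, seed=5)
    return simulate_genotypes(cfg), cfg
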