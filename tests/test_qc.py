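"""QC filters, the Hardy–Weinberg exact test against an exact-integer
enumeration oracle, the cohort split, and covariate balance checks."""

from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pleiocfdr import (QCThresholds, SimulationConfig, balance_check,
                       hwe_exact_test, sample_qc, simulate_genotypes,
                       simulate_phenotypes, snp_qc, split_cohort)
from pleiocfdr.synthdata import MISSING

from conftest import make_genotypes


def hwe_oracle_distribution(n: int, n_rare: int) -> dict:
    """Independent enumeration oracle: for ``n`` genotypes carrying
    ``n_rare`` copies of the rarer allele, the exact two-sided p-value
    for every attainable heterozygote count, from integer factorials."""
    from bisect import bisect_right
    from itertools import accumulate

    hs = list(range(n_rare % 2, n_rare + 1, 2))
    weights = []
    for h in hs:
        ha = (n_rare - h) // 2
        hb = n - ha - h
        weights.append((factorial(n) // (factorial(ha) * factorial(h)
                                         * factorial(hb))) * 2 ** h)
    total = sum(weights)
    sorted_w = sorted(weights)
    prefix = [0] + list(accumulate(sorted_w))
    out = {}
    for h, w in zip(hs, weights):
        num = prefix[bisect_right(sorted_w, w)]
        out[h] = float(Fraction(num, total))
    return out


def hwe_oracle(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    n = n_hom_major + n_het + n_hom_minor
    n_rare = min(2 * n_hom_minor + n_het, 2 * n_hom_major + n_het)
    if n_rare == 0:
        return 1.0
    return hwe_oracle_distribution(n, n_rare)[n_het]


class TestHWEExactTest:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(100, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 57) == 1.0

    @given(st.integers(0, 80), st.integers(0, 80), st.integers(0, 80))
    @settings(max_examples=200, deadline=None)
    def test_allele_label_symmetry(self, a, b, c):
        if a + b + c == 0:
            return
        assert hwe_exact_test(a, b, c) == pytest.approx(
            hwe_exact_test(c, b, a), abs=1e-14)

    def test_matches_enumeration_oracle_on_large_triple(self):
        assert hwe_exact_test(1469, 138, 5) == pytest.approx(
            hwe_oracle(1469, 138, 5), abs=1e-12)

    def test_matches_oracle_small_sweep(self):
        """Exhaustive agreement for all configurations with <= 60
        genotypes (the full sweep to 200 runs with the acceptance
        suite)."""
        for n in range(1, 61):
            for n_rare in range(1, n + 1):
                want = hwe_oracle_distribution(n, n_rare)
                for h, p in want.items():
                    hom_minor = (n_rare - h) // 2
                    hom_major = n - hom_minor - h
                    assert hwe_exact_test(hom_major, h, hom_minor) == \
                        pytest.approx(p, abs=1e-12)

    def test_agrees_with_chi_square_at_large_counts(self):
        """Asymptotic consistency: for large balanced counts the exact p
        and the 1-df chi-square HWE p differ by < 0.02."""
        for counts in [(4000, 3900, 1000), (5000, 2100, 200),
                       (8000, 1900, 120)]:
            n = sum(counts)
            f = (counts[1] + 2 * counts[2]) / (2 * n)
            exp = np.array([(1 - f) ** 2, 2 * f * (1 - f), f ** 2]) * n
            chi2 = float(((np.array(counts) - exp) ** 2 / exp).sum())
            p_chi = stats.chi2.sf(chi2, df=1)
            assert hwe_exact_test(*counts) == pytest.approx(p_chi,
                                                            abs=0.02)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)


class TestSnpQC:
    def test_known_failures_flagged(self):
        """Hand-built panel: SNP 1 misses 3/100 calls, SNP 2 is
        monomorphic, SNP 3 violates HWE grossly; the rest are clean."""
        rng = np.random.default_rng(0)
        n = 100
        clean = rng.binomial(2, 0.3, size=(n, 3)).astype(np.int8)
        d = np.column_stack([
            clean[:, 0],
            clean[:, 1],              # SNP 1: gets missing calls below
            np.zeros(n, np.int8),     # SNP 2: minor-allele count 0
            np.repeat([0, 2], n // 2).astype(np.int8),  # SNP 3: no hets
            clean[:, 2],
        ])
        d[:3, 1] = MISSING
        G = make_genotypes(d)
        rep = snp_qc(G)
        assert list(rep.mask) == [True, False, False, False, True]
        assert rep.removed["missing_rate"] == 1
        assert rep.removed["maf"] == 1
        assert rep.removed["hwe"] == 1
        assert rep.stats.loc[1, "missing_rate"] == pytest.approx(0.03)

    def test_clean_panel_retained_and_idempotent(self, small_cohort):
        G, _ = small_cohort
        rep = snp_qc(G)
        G2 = G.subset(snp_mask=rep.mask)
        rep2 = snp_qc(G2)
        assert rep2.n_removed == 0

    def test_maf_zero_excluded_at_boundary(self):
        d = np.zeros((50, 1), dtype=np.int8)
        rep = snp_qc(make_genotypes(d))
        assert not rep.mask[0]
        assert rep.stats.loc[0, "maf"] == 0.0


class TestSampleQC:
    def _cohort(self, n=50, m=100):
        rng = np.random.default_rng(1)
        G = make_genotypes(rng.binomial(2, 0.3, size=(n, m)))
        phenos = pd.DataFrame(
            {"aam": 13.0, "t2dm": 0, "bfp": 30.0, "fbg": 95.0,
             "hba1c": 5.5, "age": 50.0, "bmi": 24.0, "education": 3},
            index=pd.Index(G.sample_ids, name="sample_id"))
        return G, phenos

    def test_fully_observed_all_retained(self):
        G, ph = self._cohort()
        rep = sample_qc(G, ph)
        assert rep.mask.all()

    def test_missing_phenotype_excluded(self):
        G, ph = self._cohort()
        ph.iloc[4, ph.columns.get_loc("aam")] = np.nan
        rep = sample_qc(G, ph)
        assert not rep.mask[4] and rep.mask.sum() == len(ph) - 1
        assert rep.removed["phenotype"] == 1

    def test_exactly_two_percent_missing_excluded(self):
        """The exclusion rule is >= 2%, so exactly 2% missing genotypes
        drops the sample."""
        G, ph = self._cohort(n=50, m=100)
        G.dosages[7, :2] = MISSING  # 2/100 = 2% exactly
        rep = sample_qc(G, ph)
        assert not rep.mask[7] and rep.mask.sum() == 49

    def test_id_mismatch_rejected(self):
        G, ph = self._cohort()
        ph.index = [f"X{i}" for i in range(len(ph))]
        with pytest.raises(ValueError, match="sample_ids"):
            sample_qc(G, ph)


class TestSplitCohort:
    def test_odd_n_sizes(self):
        a, b = split_cohort(["x", "y", "z"], seed=0)
        assert sorted(map(len, (a, b))) == [1, 2]
        assert set(a) | set(b) == {"x", "y", "z"}
        assert not set(a) & set(b)

    def test_deterministic_under_seed(self):
        ids = [f"s{i}" for i in range(101)]
        assert split_cohort(ids, 7) == split_cohort(ids, 7)
        assert split_cohort(ids, 7) != split_cohort(ids, 8)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            split_cohort(["only"], seed=0)


class TestBalanceCheck:
    def _phenos(self, n, seed=0, shift=0.0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "age": rng.normal(50 + shift * 10, 10, n),
            "bmi": rng.normal(24, 3, n),
            "education": rng.integers(1, 7, n),
        })

    def test_identical_tables_give_p_one(self):
        ph = self._phenos(200)
        out = balance_check(ph, ph.copy(), ["age", "bmi", "education"])
        out = out.set_index("covariate")
        assert out.loc["age", "statistic"] == pytest.approx(0.0)
        assert out.loc["education", "p"] == pytest.approx(1.0)

    def test_gross_imbalance_detected(self):
        a = self._phenos(500, seed=1)
        b = self._phenos(500, seed=2, shift=5.0)  # 5 sd shift in age
        out = balance_check(a, b, ["age"]).set_index("covariate")
        assert out.loc["age", "p"] < 1e-10

    def test_null_calibration_over_random_splits(self):
        """Random halves of one homogeneous cohort reject at ~5%."""
        ph = self._phenos(800, seed=3)
        ph.index = [f"s{i}" for i in range(len(ph))]
        rejections = {c: 0 for c in ("age", "bmi", "education")}
        n_seeds = 200
        for seed in range(n_seeds):
            ids1, ids2 = split_cohort(list(ph.index), seed)
            out = balance_check(ph.loc[ids1], ph.loc[ids2],
                                list(rejections))
            for _, row in out.iterrows():
                rejections[row["covariate"]] += row["p"] < 0.05
        for cov, k in rejections.items():
            # 3 binomial SEs around 5% of 200
            assert 0 <= k <= 0.05 * n_seeds + 3 * np.sqrt(
                n_seeds * 0.05 * 0.95), cov

    def test_absent_covariate_rejected(self):
        ph = self._phenos(50)
        with pytest.raises(ValueError, match="waistline"):
            balance_check(ph, ph, ["waistline"])
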