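"""Mixed-model association: filters, kinship, LRT and scan behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from goldmapper import (
    GenotypeMatrix,
    compute_kinship,
    filter_variants,
    gwas_scan,
    lmm_lrt,
)
from goldmapper.association import MIN_POSITIVE_P


def matrix_from(dosages, positions=None):
    dosages = np.asarray(dosages, dtype=float)
    m, n = dosages.shape
    variant_ids = [f"v{i}" for i in range(m)]
    samples = [f"s{i}" for i in range(n)]
    variants = pd.DataFrame(
        {"chrom": "chr11",
         "pos": positions if positions is not None else np.arange(1, m + 1)},
        index=variant_ids)
    return GenotypeMatrix(pd.DataFrame(dosages, index=variant_ids, columns=samples),
                          variants)


def ols_minus_log10_p(y, x):
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss1 = float(((y - X @ beta) ** 2).sum())
    rss0 = float(((y - y.mean()) ** 2).sum())
    lrt = n * np.log(rss0 / rss1)
    return -np.log10(stats.chi2.sf(lrt, df=1))


class TestFilters:
    def test_maf_and_missingness_rules(self):
        n = 100
        rng = np.random.default_rng(0)
        low_maf = np.zeros(n); low_maf[:8] = 1.0            # MAF 0.04
        ok = rng.binomial(2, 0.3, n).astype(float)           # common variant
        missing = ok.copy(); missing[:25] = np.nan           # 25% missing
        mono = np.zeros(n)                                   # monomorphic
        gm = matrix_from([low_maf, ok, missing, mono])
        kept = filter_variants(gm)
        assert list(kept.dosages.index) == ["v1"]

    def test_boundary_values_are_inclusive(self):
        n = 100
        at_maf = np.zeros(n); at_maf[:10] = 1.0              # MAF exactly 0.05
        rng = np.random.default_rng(1)
        at_miss = rng.binomial(2, 0.4, n).astype(float)
        at_miss[:20] = np.nan                                # exactly 20% missing
        kept = filter_variants(matrix_from([at_maf, at_miss]))
        assert len(kept.dosages) == 2

    def test_all_removed_warns_and_returns_empty(self, caplog):
        gm = matrix_from([np.zeros(50)])
        with caplog.at_level("WARNING"):
            kept = filter_variants(gm)
        assert kept.n_variants == 0
        assert "removed" in caplog.text


class TestKinship:
    def test_all_heterozygous_variant_contributes_nothing(self):
        K = compute_kinship(matrix_from([np.ones(10)]))
        assert np.allclose(K.to_numpy(), 0.0)

    def test_identical_samples_have_equal_entries(self):
        rng = np.random.default_rng(2)
        col = rng.binomial(2, 0.4, size=30).astype(float)
        dosages = np.column_stack([col, col])               # two clone samples
        K = compute_kinship(matrix_from(dosages))
        k = K.to_numpy()
        assert k[0, 0] == pytest.approx(k[1, 1])
        assert k[0, 1] == pytest.approx(k[0, 0])

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(3)
        dosages = rng.binomial(2, 0.3, size=(50, 20)).astype(float)
        K = compute_kinship(matrix_from(dosages)).to_numpy()
        X = dosages - dosages.mean(axis=1, keepdims=True)
        naive = np.zeros((20, 20))
        for k in range(50):
            naive += np.outer(X[k], X[k])
        naive /= 50
        assert np.abs(K - naive).max() < 1e-10

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="two samples"):
            compute_kinship(matrix_from(np.zeros((3, 1))))


class TestLmmLrt:
    def test_identity_kinship_equals_ols(self, rng):
        n = 150
        for _ in range(5):
            y = rng.normal(size=n)
            x = rng.binomial(2, 0.3, size=n).astype(float)
            res = lmm_lrt(y, x, kinship=np.eye(n))
            assert res.minus_log10_p == pytest.approx(
                ols_minus_log10_p(y, x), abs=1e-6)

    def test_perfect_fit_reports_underflow_floor(self, rng):
        x = rng.binomial(2, 0.4, size=80).astype(float)
        res = lmm_lrt(x.copy(), x, kinship=np.eye(80))
        assert res.p_value == MIN_POSITIVE_P
        assert res.underflow

    def test_constant_dosage_flagged_untestable(self, rng):
        res = lmm_lrt(rng.normal(size=40), np.ones(40), kinship=np.eye(40))
        assert res.untestable

    def test_lrt_invariant_under_affine_phenotype_rescaling(self, rng):
        n = 120
        dosages = rng.binomial(2, 0.3, size=(60, n)).astype(float)
        K = compute_kinship(matrix_from(dosages)).to_numpy()
        y = rng.normal(size=n) + 0.4 * dosages[0]
        a = lmm_lrt(y, dosages[0], kinship=K)
        b = lmm_lrt(3.5 * y - 7.0, dosages[0], kinship=K)
        assert b.lrt == pytest.approx(a.lrt, abs=1e-6)

    def test_null_lrt_mean_matches_chi_square(self, rng):
        # under the null the LRT is asymptotically chi-square(1), mean 1
        n, reps = 150, 400
        lrts = []
        eye = np.eye(n)
        for _ in range(reps):
            y = rng.normal(size=n)
            x = rng.binomial(2, 0.3, size=n).astype(float)
            lrts.append(lmm_lrt(y, x, kinship=eye).lrt)
        assert np.mean(lrts) == pytest.approx(1.0, abs=0.25)


class TestScan:
    def test_causal_variant_ranks_first(self, rng):
        n, m = 300, 500
        mafs = rng.uniform(0.05, 0.5, size=m)
        background = rng.binomial(2, mafs[:, None], size=(m, n)).astype(float)
        causal = rng.binomial(2, 0.2, size=n).astype(float)
        phenotype = (causal > 0).astype(float)
        flip = rng.random(n) < 0.04
        phenotype[flip] = 1.0 - phenotype[flip]
        gm = matrix_from(np.vstack([background, causal]),
                         positions=list(range(1, m + 1)) + [10**6])
        scan = gwas_scan(gm, pd.Series(phenotype, index=gm.samples))
        top = scan.loc[scan["minus_log10_p"].idxmax()]
        assert top["variant"] == f"v{m}"
        assert scan["pos"].is_monotonic_increasing

    def test_single_retained_variant(self, rng):
        x = rng.binomial(2, 0.3, size=60).astype(float)
        gm = matrix_from([x])
        scan = gwas_scan(gm, pd.Series(rng.normal(size=60), index=gm.samples))
        assert len(scan) == 1

    def test_identity_scan_equals_ols_scan(self, rng):
        n, m = 120, 40
        dosages = rng.binomial(2, rng.uniform(0.1, 0.5, m)[:, None],
                               size=(m, n)).astype(float)
        y = rng.normal(size=n)
        gm = matrix_from(dosages)
        scan = gwas_scan(gm, pd.Series(y, index=gm.samples), no_kinship=True)
        for _, row in scan.iterrows():
            x = dosages[int(row["variant"][1:])]
            assert row["minus_log10_p"] == pytest.approx(
                ols_minus_log10_p(y, x), abs=1e-6)

    def test_missing_dosages_mean_imputed_not_dropped(self, rng):
        x = rng.binomial(2, 0.4, size=100).astype(float)
        x_missing = x.copy(); x_missing[:10] = np.nan        # 10% missing: retained
        gm = matrix_from([x_missing])
        y = x + rng.normal(scale=0.5, size=100)
        scan = gwas_scan(gm, pd.Series(y, index=gm.samples), no_kinship=True)
        assert len(scan) == 1
        assert scan["p_value"].iloc[0] < 1e-6
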