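import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pedqtl import (
    VarianceModel,
    define_loci,
    gls_scan,
    inflation_factor,
    maf,
    significance_thresholds,
    variance_explained,
)
from pedqtl.association import CHI2_1DF_MEDIAN, gls_scan_dense
from pedqtl.relationship import RelationshipMatrix

from conftest import dense_gls_oracle, make_genotypes

# ---------------------------------------------------------------------------
# the n=6 half-sib fixture: A written down from Wright's coefficients,
# expected values frozen from a literal dense-inversion evaluation of the
# GLS equations (independent oracle, explicit matrix inverses)
# ---------------------------------------------------------------------------

FIX_A = np.array(
    [
        [1.0, 0.0, 0.0, 0.0, 0.5, 0.5],
        [0.0, 1.0, 0.0, 0.0, 0.5, 0.0],
        [0.0, 0.0, 1.0, 0.0, 0.0, 0.5],
        [0.0, 0.0, 0.0, 1.0, 0.0, 0.0],
        [0.5, 0.5, 0.0, 0.0, 1.0, 0.25],
        [0.5, 0.0, 0.5, 0.0, 0.25, 1.0],
    ]
)
FIX_Y = np.array([1.3, -0.2, 0.5, 2.0, 0.9, -1.1])
FIX_DOSAGES = np.array(
    [[0, 1], [1, 2], [2, 0], [1, 1], [0, 2], [2, 0]], dtype=float
)
FIX_H2, FIX_S2 = 0.5, 1.7
# frozen oracle output (beta, se, chi2) per variant:
FIX_EXPECTED = [
    (-0.8576878612716763, 0.6590411672388963, 1.6936881135945083),
    (0.3863636363636364, 0.7087120199860641, 0.2972027972027972),
]


def _fixture_vm(h2=FIX_H2, s2=FIX_S2, A=FIX_A):
    ids = [f"a{i}" for i in range(len(A))]
    return VarianceModel(h2, s2, RelationshipMatrix(ids, A))


class TestGlsScan:
    def test_matches_frozen_dense_oracle(self):
        g = make_genotypes(FIX_DOSAGES)
        res = gls_scan(g, FIX_Y, _fixture_vm())
        for j, (beta, se, chi2) in enumerate(FIX_EXPECTED):
            assert res.loc[j, "beta"] == pytest.approx(beta, abs=1e-10)
            assert res.loc[j, "se"] == pytest.approx(se, abs=1e-10)
            assert res.loc[j, "chi2"] == pytest.approx(chi2, abs=1e-10)

    def test_matches_live_oracle_random_20_animals(self):
        rng = np.random.default_rng(7)
        n, m = 20, 15
        # random PSD relationship-like matrix with unit-ish diagonal
        B = rng.normal(size=(n, n)) * 0.1
        A = B @ B.T
        A = A / np.sqrt(np.outer(np.diag(A), np.diag(A)))
        d = rng.integers(0, 3, size=(n, m)).astype(float)
        d[rng.random((n, m)) < 0.1] = np.nan
        y = rng.normal(size=n)
        g = make_genotypes(d)
        vm = _fixture_vm(h2=0.6, s2=2.3, A=A)
        res = gls_scan(g, y, vm)
        dense = gls_scan_dense(g, y, vm)
        for j in range(m):
            if np.isnan(res.loc[j, "beta"]):
                assert np.isnan(dense.loc[j, "beta"])
                continue
            b, se, chi2 = dense_gls_oracle(A, y, d[:, j], 0.6, 2.3)
            assert res.loc[j, "beta"] == pytest.approx(b, abs=1e-10)
            assert res.loc[j, "se"] == pytest.approx(se, abs=1e-10)
            assert res.loc[j, "chi2"] == pytest.approx(chi2, abs=1e-10)
            assert dense.loc[j, "beta"] == pytest.approx(b, abs=1e-10)

    def test_h2_zero_reduces_to_ols(self):
        g = make_genotypes(FIX_DOSAGES)
        res = gls_scan(g, FIX_Y, _fixture_vm(h2=0.0))
        for j in range(2):
            x = FIX_DOSAGES[:, j] - FIX_DOSAGES[:, j].mean()
            X = np.column_stack([np.ones(6), x])
            C = np.linalg.inv(X.T @ X)
            b_ols = (C @ X.T @ FIX_Y)[1]
            se_ols = np.sqrt(FIX_S2 * C[1, 1])
            assert res.loc[j, "beta"] == pytest.approx(b_ols, abs=1e-12)
            assert res.loc[j, "se"] == pytest.approx(se_ols, abs=1e-12)

    def test_identity_A_equals_h2_zero(self):
        g = make_genotypes(FIX_DOSAGES)
        res_h0 = gls_scan(g, FIX_Y, _fixture_vm(h2=0.0, A=np.eye(6)))
        res_ai = gls_scan(g, FIX_Y, _fixture_vm(h2=0.7, A=np.eye(6)))
        np.testing.assert_allclose(res_ai["beta"], res_h0["beta"], atol=1e-12)
        np.testing.assert_allclose(res_ai["se"], res_h0["se"], atol=1e-12)

    def test_constant_phenotype_gives_zero_effects(self):
        g = make_genotypes(FIX_DOSAGES)
        res = gls_scan(g, np.full(6, 3.3), _fixture_vm())
        np.testing.assert_allclose(res["beta"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["chi2"], 0.0, atol=1e-12)

    def test_affine_rescaling_of_y(self):
        g = make_genotypes(FIX_DOSAGES)
        a, b = -2.5, 7.0
        res1 = gls_scan(g, FIX_Y, _fixture_vm())
        res2 = gls_scan(g, a * FIX_Y + b, _fixture_vm(s2=a**2 * FIX_S2))
        np.testing.assert_allclose(res2["beta"], a * res1["beta"], atol=1e-10)
        np.testing.assert_allclose(res2["se"], abs(a) * res1["se"], atol=1e-10)
        np.testing.assert_allclose(res2["chi2"], res1["chi2"], atol=1e-10)
        np.testing.assert_allclose(res2["p"], res1["p"], atol=1e-10)

    def test_monomorphic_variant_missing_stats(self):
        d = FIX_DOSAGES.copy()
        d[:, 1] = 2.0
        res = gls_scan(make_genotypes(d), FIX_Y, _fixture_vm())
        assert res.loc[1, ["beta", "se", "chi2", "p"]].isna().all()
        assert res.loc[1, "n_used"] == 6

    def test_missing_dosages_mean_imputed(self):
        d = FIX_DOSAGES.copy()
        d[0, 0] = np.nan
        res = gls_scan(make_genotypes(d), FIX_Y, _fixture_vm())
        b, se, chi2 = dense_gls_oracle(FIX_A, FIX_Y, d[:, 0], FIX_H2, FIX_S2)
        assert res.loc[0, "beta"] == pytest.approx(b, abs=1e-10)
        assert res.loc[0, "n_used"] == 5

    def test_nonfinite_phenotype_rejected(self):
        g = make_genotypes(FIX_DOSAGES)
        y = FIX_Y.copy()
        y[2] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            gls_scan(g, y, _fixture_vm())

    def test_misaligned_animals_rejected(self):
        g = make_genotypes(FIX_DOSAGES, animal_ids=[f"z{i}" for i in range(6)])
        with pytest.raises(ValueError, match="animal order"):
            gls_scan(g, FIX_Y, _fixture_vm())


class TestMaf:
    def test_counting_example(self):
        g = make_genotypes(np.array([[0.0], [1.0], [2.0], [2.0]]))
        row = maf(g).iloc[0]
        assert row["alt_freq"] == pytest.approx(0.625)
        assert row["maf"] == pytest.approx(0.375)
        assert row["minor_is_ref"]

    def test_all_reference(self):
        g = make_genotypes(np.zeros((4, 1)))
        row = maf(g).iloc[0]
        assert row["maf"] == 0.0
        assert not row["minor_is_ref"]

    def test_against_allele_counting_oracle(self):
        rng = np.random.default_rng(12)
        d = rng.integers(0, 3, size=(50, 20)).astype(float)
        d[rng.random(d.shape) < 0.2] = np.nan
        g = make_genotypes(d)
        table = maf(g)
        for j in range(20):
            col = d[:, j]
            called = col[np.isfinite(col)]
            freq = called.sum() / (2 * len(called))
            assert table.loc[j, "alt_freq"] == pytest.approx(freq, abs=1e-12)
            assert table.loc[j, "maf"] == pytest.approx(min(freq, 1 - freq), abs=1e-12)

    def test_all_missing_variant_nan(self):
        g = make_genotypes(np.array([[np.nan], [np.nan]]))
        assert np.isnan(maf(g).loc[0, "maf"])


class TestInflationFactor:
    def test_unit_lambda_at_theoretical_median(self):
        assert inflation_factor(np.full(101, 0.45494)) == pytest.approx(1.0)

    def test_doubled_median(self):
        assert inflation_factor(np.full(11, 0.90988)) == pytest.approx(2.0)

    def test_null_simulation_near_one(self):
        rng = np.random.default_rng(2024)
        draws = rng.chisquare(df=1, size=100_000)
        assert 0.97 <= inflation_factor(draws) <= 1.03

    def test_nan_entries_dropped(self):
        x = np.array([np.nan, 0.45494, 0.45494, 0.45494])
        assert inflation_factor(x) == pytest.approx(1.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            inflation_factor(np.array([]))
        with pytest.raises(ValueError):
            inflation_factor(np.array([np.nan]))

    def test_theoretical_median_constant(self):
        assert CHI2_1DF_MEDIAN == 0.45494
        assert CHI2_1DF_MEDIAN == pytest.approx(stats.chi2.ppf(0.5, 1), abs=5e-6)


class TestSignificanceThresholds:
    def test_genomewide_bonferroni(self):
        rep = significance_thresholds(1_090_999, alpha=0.05, lam=1.0)
        assert float(f"{rep.bonferroni_p:.2e}") == 4.58e-8
        assert rep.adjusted_p == pytest.approx(rep.bonferroni_p, rel=1e-9)

    def test_window_bonferroni(self):
        rep = significance_thresholds(197_338, alpha=0.05)
        assert float(f"{rep.bonferroni_p:.2e}") == 2.53e-7

    def test_priority_threshold(self):
        rep = significance_thresholds(1_090_999, alpha=0.05)
        # 10^(-1.5 * -log10(4.58e-8)) ~ 9.8e-12, by hand
        assert rep.priority_p == pytest.approx(9.81e-12, rel=5e-3)
        assert rep.priority_p < rep.bonferroni_p

    def test_adjusted_strictly_decreasing_in_lambda(self):
        lams = [1.0, 1.5, 2.0, 2.25, 2.28, 3.0]
        vals = [significance_thresholds(10_000, lam=l).adjusted_p for l in lams]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_lambda_below_one_passed_through(self):
        rep = significance_thresholds(100, lam=0.8)
        assert rep.adjusted_p > rep.bonferroni_p

    def test_input_validation(self):
        with pytest.raises(ValueError):
            significance_thresholds(0)
        with pytest.raises(ValueError):
            significance_thresholds(10, alpha=1.5)


def greedy_loci_oracle(rows, threshold, window_bp):
    """Brute-force greedy enumeration over (variant_id, chrom, pos, p)."""
    remaining = [r for r in rows if r[3] is not None and r[3] < threshold]
    pool = [r for r in rows if r[3] is not None]
    loci = []
    while remaining:
        tag = min(remaining, key=lambda r: (r[3], r[1], r[2]))
        lo, hi = tag[2] - window_bp // 2, tag[2] + window_bp // 2
        loci.append(tag[0])
        pool = [r for r in pool if not (r[1] == tag[1] and lo <= r[2] < hi)]
        remaining = [r for r in pool if r[3] < threshold]
    return sorted(loci)


def _assoc_frame(rows):
    df = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "p"])
    df["beta"] = 0.1
    df["se"] = 0.1
    df["chi2"] = 1.0
    df["n_used"] = 10
    return df


class TestDefineLoci:
    def test_two_distant_peaks(self):
        rows = [
            ("v1", "1", 1_000_000, 1e-10),
            ("v2", "1", 3_000_000, 1e-9),
            ("v3", "1", 3_100_000, 1e-3),
        ]
        loci = define_loci(_assoc_frame(rows), threshold_p=1e-8)
        assert [l.tag_variant for l in loci] == ["v1", "v2"]
        assert loci[0].window == (500_000, 1_500_000)

    def test_nothing_significant(self):
        rows = [("v1", "1", 100, 0.5)]
        assert define_loci(_assoc_frame(rows), threshold_p=1e-8) == []

    def test_close_peaks_absorbed(self):
        rows = [
            ("v1", "1", 1_000_000, 1e-10),
            ("v2", "1", 1_400_000, 1e-9),
        ]
        loci = define_loci(_assoc_frame(rows), threshold_p=1e-8)
        assert len(loci) == 1
        assert loci[0].tag_variant == "v1"
        assert "v2" in loci[0].member_variants

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = 120
        rows = [
            (f"v{j}", str(rng.integers(1, 4)), int(rng.integers(1, 5_000_000)),
             float(10 ** -rng.uniform(0, 12)))
            for j in range(m)
        ]
        rows.sort(key=lambda r: (r[1], r[2]))
        rows = [
            (f"v{j}", c, p + j, pv)  # ensure unique increasing positions
            for j, (_, c, p, pv) in enumerate(rows)
        ]
        loci = define_loci(_assoc_frame(rows), threshold_p=1e-6)
        expected = greedy_loci_oracle(rows, 1e-6, 1_000_000)
        assert sorted(l.tag_variant for l in loci) == expected

    def test_tags_not_shared_between_loci(self):
        rows = [
            ("v1", "1", 1_000_000, 1e-10),
            ("v2", "2", 1_000_000, 1e-10),
        ]
        loci = define_loci(_assoc_frame(rows), threshold_p=1e-8)
        tags = [l.tag_variant for l in loci]
        assert len(tags) == len(set(tags)) == 2


class TestVarianceExplained:
    def test_arithmetic(self):
        assert variance_explained(1.0, 0.5, 2.0) == pytest.approx(0.25)

    def test_zero_effect(self):
        assert variance_explained(0.0, 0.3, 1.0) == 0.0

    def test_boundary_frequency_warns(self):
        with pytest.warns(UserWarning, match="boundary"):
            assert variance_explained(1.0, 0.0, 1.0) == 0.0

    def test_additivity_against_joint_r2(self):
        rng = np.random.default_rng(42)
        n = 4000
        p1, p2, b1, b2 = 0.3, 0.6, 0.4, -0.3
        x1 = rng.binomial(2, p1, n).astype(float)
        x2 = rng.binomial(2, p2, n).astype(float)
        y = b1 * x1 + b2 * x2 + rng.normal(0, 1.0, n)
        s2 = y.var(ddof=1)
        ve = variance_explained(b1, x1.mean() / 2, s2) + variance_explained(
            b2, x2.mean() / 2, s2
        )
        X = np.column_stack([np.ones(n), x1, x2])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        r2 = 1 - resid.var() / y.var()
        assert ve == pytest.approx(r2, rel=0.10)
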