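import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from urinmr import epistats as es
from urinmr import synthspec as ss


class TestLogSdScale:
    def test_hand_computed_column(self):
        df = pd.DataFrame({"a": [1.0, math.e, math.e**2]})
        scaled = es.log_sd_scale(df)
        # log -> [0,1,2]; mean 1; sample SD (n-1) = 1 -> [-1,0,1]
        np.testing.assert_allclose(scaled.data["a"], [-1.0, 0.0, 1.0], atol=1e-12)
        assert scaled.data["a"].mean() == pytest.approx(0.0, abs=1e-10)
        assert scaled.data["a"].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            es.log_sd_scale(pd.DataFrame({"a": [2.0, 2.0, 2.0]}))

    def test_nonpositive_strict_names_cell(self):
        df = pd.DataFrame({"a": [1.0, 0.0]}, index=["s1", "s2"])
        with pytest.raises(ValueError, match="s2"):
            es.log_sd_scale(df)

    def test_drop_policy(self):
        df = pd.DataFrame({"a": [1.0, 0.0, 2.0, 4.0]})
        scaled = es.log_sd_scale(df, pseudo_policy="drop")
        assert scaled.data["a"].isna().sum() == 1

    def test_rescale_without_relog_idempotent(self, rng):
        df = pd.DataFrame(rng.lognormal(0, 1, (50, 3)), columns=list("abc"))
        once = es.log_sd_scale(df)
        twice = es.log_sd_scale(once.data, log=False)
        pd.testing.assert_frame_equal(once.data, twice.data, atol=1e-10)


class TestPartialCorrelation:
    def test_orthogonal_covariate_equals_marginal(self, rng):
        n = 400
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        z = rng.normal(size=n)
        # orthogonalize z against x and y exactly
        design = np.column_stack([np.ones(n), x, y])
        z = z - design @ np.linalg.lstsq(design, z, rcond=None)[0]
        r_marg, _, _ = es.partial_correlation(x, y)
        r_part, _, _ = es.partial_correlation(x, y, z)
        assert r_part == pytest.approx(r_marg, abs=1e-10)

    def test_self_correlation_one(self, rng):
        x = rng.normal(size=50)
        r, p, n = es.partial_correlation(x, x)
        assert r == 1.0
        assert p == 0.0

    def test_twenty_point_fixture_matches_two_step_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=20)
        y = rng.normal(size=20) + 0.4 * x
        z = rng.normal(size=(20, 2))
        r, p, n = es.partial_correlation(x, y, z)
        # independent oracle: residualize each on [1, z] then Pearson
        design = np.column_stack([np.ones(20), z])
        hat = design @ np.linalg.pinv(design)
        rx = x - hat @ x
        ry = y - hat @ y
        r_oracle = np.corrcoef(rx, ry)[0, 1]
        assert r == pytest.approx(r_oracle, abs=1e-12)
        df = 20 - 2 - 2
        t = r_oracle * math.sqrt(df / (1 - r_oracle**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df), rel=1e-10)

    def test_exchangeable_in_x_y(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        z = rng.normal(size=30)
        assert es.partial_correlation(x, y, z)[0] == pytest.approx(
            es.partial_correlation(y, x, z)[0], abs=1e-12
        )

    def test_affine_covariate_invariance(self, rng):
        x = rng.normal(size=60)
        y = rng.normal(size=60)
        z = rng.normal(size=60)
        r1, _, _ = es.partial_correlation(x, y, z)
        r2, _, _ = es.partial_correlation(x, y, 3.0 * z - 7.0)
        assert r1 == pytest.approx(r2, abs=1e-10)

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            es.partial_correlation([1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                                   np.ones((3, 2)))


class TestCorrelationMap:
    def test_identity_map(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        scaled = es.log_sd_scale(np.exp(df))
        cmap = es.correlation_map(scaled)
        np.testing.assert_allclose(np.diag(cmap.r.values), 1.0)
        np.testing.assert_allclose(cmap.r.values, cmap.r.values.T, atol=1e-12)
        assert np.abs(cmap.r.values).max() <= 1.0 + 1e-12

    def test_null_median_abs_r(self, rng):
        # independent Gaussians, n=995: median |r| ~ 0.6745/sqrt(n) = 0.0214
        n, m = 995, 30
        df = pd.DataFrame(
            rng.normal(size=(n, m)), columns=[f"m{i}" for i in range(m)]
        )
        scaled = es.log_sd_scale(np.exp(df))
        cmap = es.correlation_map(scaled)
        assert cmap.median_abs_r == pytest.approx(0.6745 / math.sqrt(n), rel=0.25)

    def test_cluster_ordering_is_permutation(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        scaled = es.log_sd_scale(np.exp(df))
        cmap = es.correlation_map(scaled, ordering="cluster")
        assert sorted(cmap.ordering) == list("abcde")

    def test_manual_ordering_respected(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        scaled = es.log_sd_scale(np.exp(df))
        cmap = es.correlation_map(scaled, ordering=["c", "a", "b"])
        assert list(cmap.r.index) == ["c", "a", "b"]

    def test_cross_fluid_block_contrast(self, rng):
        # urine-like independent columns vs serum-like correlated block:
        # median |r|(urine) < median |r|(serum); cross-fluid weakest
        n = 500
        base_u = rng.normal(size=(n, 1))
        urine = 0.3 * base_u + rng.normal(size=(n, 8))
        base = rng.normal(size=(n, 1))
        serum = 0.8 * base + 0.35 * rng.normal(size=(n, 8))
        cols_u = [f"u{i}" for i in range(8)]
        cols_s = [f"s{i}" for i in range(8)]
        df = pd.DataFrame(np.hstack([urine, serum]), columns=cols_u + cols_s)
        scaled = es.log_sd_scale(np.exp(df / 4))
        um = es.correlation_map(scaled, subset_a=cols_u)
        sm = es.correlation_map(scaled, subset_a=cols_s)
        xm = es.correlation_map(scaled, subset_a=cols_u, subset_b=cols_s)
        assert xm.median_abs_r < um.median_abs_r < sm.median_abs_r


class TestEffectiveTests:
    def test_independent_columns_full_rank(self, rng):
        n, m = 3000, 43
        mat = rng.normal(size=(n, m))
        assert es.effective_tests(mat) == 43

    def test_perfectly_correlated_pair(self, rng):
        x = rng.normal(size=200)
        mat = np.column_stack([x, 2.0 * x])
        assert es.effective_tests(mat) == 1

    def test_rank3_construction(self, rng):
        n = 400
        basis = rng.normal(size=(n, 3))
        mix = rng.normal(size=(3, 10))
        mat = basis @ mix + 1e-8 * rng.normal(size=(n, 10))
        assert es.effective_tests(mat) == 3

    def test_nan_rejected(self):
        mat = np.ones((10, 3))
        mat[0, 0] = np.nan
        with pytest.raises(ValueError):
            es.effective_tests(mat)

    def test_brute_force_equivalence_random_matrices(self, rng):
        for _ in range(5):
            mat = rng.normal(size=(60, 10)) @ rng.normal(size=(10, 10))
            m_eff = es.effective_tests(mat, threshold=0.99)
            # independent oracle: explicit eigenvalue accumulation
            corr = np.corrcoef(mat, rowvar=False)
            eig = sorted(np.linalg.eigvals(corr).real, reverse=True)
            total = sum(eig)
            acc, k = 0.0, 0
            for lam in eig:
                acc += lam
                k += 1
                if acc / total > 0.99:
                    break
            assert m_eff == k


class TestBonferroni:
    def test_printed_thresholds(self):
        assert es.bonferroni_threshold(0.05, 40, rounding=True) == pytest.approx(0.001)
        assert es.bonferroni_threshold(0.05, 27, rounding=True) == pytest.approx(0.002)
        assert es.bonferroni_threshold(0.05, 66, rounding=True) == pytest.approx(0.0008)
        assert es.bonferroni_threshold(5e-8, 40) == pytest.approx(1.25e-9, rel=1e-12)

    def test_unrounded(self):
        assert es.bonferroni_threshold(0.05, 40) == pytest.approx(0.00125)

    def test_validation(self):
        with pytest.raises(ValueError):
            es.bonferroni_threshold(1.5, 10)
        with pytest.raises(ValueError):
            es.bonferroni_threshold(0.05, 0)


class TestExposureAssociation:
    def test_null_beta_near_zero(self, rng):
        out = pd.DataFrame({"y": rng.normal(size=500)})
        expo = rng.normal(size=500)
        res = es.exposure_association(out, expo)
        assert abs(res.loc["y", "beta"]) < 3 * res.loc["y", "se"] + 0.05

    def test_attenuation_by_standardization(self, rng):
        # outcome = 0.3 x + e, then outcome SD-scaled:
        # beta -> 0.3/sqrt(0.3^2+1)
        n = 1000
        x = rng.normal(size=n)
        y = 0.3 * x + rng.normal(size=n)
        scaled = es.log_sd_scale(pd.DataFrame({"y": np.exp(y)}))
        res = es.exposure_association(scaled, x)
        expected = 0.3 / math.sqrt(0.3**2 + 1.0)
        assert res.loc["y", "beta"] == pytest.approx(expected, abs=4 * res.loc["y", "se"])

    def test_sign_antisymmetry(self, rng):
        n = 200
        x = rng.normal(size=n)
        out = pd.DataFrame({"y": 0.4 * x + rng.normal(size=n)})
        b1 = es.exposure_association(out, x).loc["y", "beta"]
        b2 = es.exposure_association(out, -x).loc["y", "beta"]
        assert b1 == pytest.approx(-b2, abs=1e-10)

    def test_constant_exposure_rejected(self, rng):
        out = pd.DataFrame({"y": rng.normal(size=10)})
        with pytest.raises(ValueError):
            es.exposure_association(out, np.ones(10))


class TestInverseNormalTransform:
    def test_middle_of_odd_n_is_zero(self):
        scores = es.inverse_normal_transform([3.0, 1.0, 2.0])
        assert scores[2] == pytest.approx(0.0, abs=1e-12)  # 2.0 is the median

    def test_rank_invariance_under_monotone_map(self, rng):
        v = rng.normal(size=31)
        s1 = es.inverse_normal_transform(v)
        s2 = es.inverse_normal_transform(np.exp(2.0 * v) + 7.0)
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_blom_constants_n5(self):
        scores = es.inverse_normal_transform([10.0, 20.0, 30.0, 40.0, 50.0])
        expected = stats.norm.ppf((np.arange(1, 6) - 0.375) / 5.25)
        np.testing.assert_allclose(scores, expected, atol=1e-12)
        np.testing.assert_allclose(
            expected, [-1.17976, -0.49720, 0.0, 0.49720, 1.17976], atol=1e-5
        )

    def test_all_tied_degenerate(self):
        np.testing.assert_array_equal(
            es.inverse_normal_transform([4.0, 4.0, 4.0]), np.zeros(3)
        )

    @given(st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=3, max_size=50,
                    unique=True))
    def test_symmetry_property(self, values):
        scores = es.inverse_normal_transform(values)
        assert abs(np.sum(scores)) < 1e-8 * max(1, len(values))


def _cohort(n=300, seed=0, n_variants=200):
    rng = np.random.default_rng(seed)
    dos, vinfo = ss.simulate_genotypes(n, n_variants, seed=seed,
                                       maf_range=(0.02, 0.5))
    pheno = pd.Series(rng.normal(size=n), index=dos.index)
    cov = pd.DataFrame({"sex": rng.integers(0, 2, n)}, index=dos.index)
    gm = es.GenotypeMatrix(dosages=dos, info=vinfo["info"],
                           chrom=vinfo["chrom"], pos=vinfo["pos"])
    return pheno, cov, gm


class TestGeneticScan:
    def test_maf_info_filters_applied(self):
        pheno, cov, gm = _cohort()
        res = es.genetic_scan(pheno, cov, gm, maf_min=0.05, info_min=0.8)
        assert (res["maf"] >= 0.05).all()
        assert (res["info"] >= 0.8).all()
        assert len(res) < gm.dosages.shape[1]

    def test_monomorphic_variant_filtered(self):
        pheno, cov, gm = _cohort(n=100, n_variants=20)
        gm.dosages.iloc[:, 0] = 0.0
        res = es.genetic_scan(pheno, cov, gm, maf_min=0.01, info_min=0.0)
        assert gm.dosages.columns[0] not in res.index

    def test_null_type_one_error(self):
        pheno, cov, gm = _cohort(n=600, seed=1, n_variants=1000)
        res = es.genetic_scan(pheno, cov, gm, maf_min=0.05, info_min=0.0)
        frac = float((res["p"] < 0.05).mean())
        assert frac == pytest.approx(0.05, abs=0.025)

    def test_null_p_uniformity_ks(self):
        # ~10^4 null tests pooled over seeds
        ps = []
        for seed in range(5):
            pheno, cov, gm = _cohort(n=250, seed=seed + 10, n_variants=2000)
            res = es.genetic_scan(pheno, cov, gm, maf_min=0.05, info_min=0.0)
            ps.append(res["p"].values)
        ps = np.concatenate(ps)
        assert len(ps) >= 5000
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_variant_reaches_genome_wide(self):
        # 15% variance explained at n=578 -> expected chi2 ~ 100; the
        # threshold 1.25e-9 needs ~37, so nearly every replicate is a hit
        hits = 0
        threshold = es.bonferroni_threshold(5e-8, 40)
        for seed in range(5):
            rng = np.random.default_rng(seed + 100)
            n = 578
            dos, vinfo = ss.simulate_genotypes(n, 50, seed=seed + 100,
                                               maf_range=(0.1, 0.5))
            g = dos.iloc[:, 0].values
            gz = (g - g.mean()) / g.std(ddof=1)
            pheno = pd.Series(
                math.sqrt(0.15) * gz + math.sqrt(0.85) * rng.normal(size=n),
                index=dos.index,
            )
            cov = pd.DataFrame({"sex": rng.integers(0, 2, n)}, index=dos.index)
            gm = es.GenotypeMatrix(dosages=dos, info=vinfo["info"])
            res = es.genetic_scan(pheno, cov, gm, maf_min=0.05, info_min=0.0)
            if res.loc[dos.columns[0], "p"] < threshold:
                hits += 1
        assert hits >= 4

    def test_misaligned_ids_rejected(self):
        pheno, cov, gm = _cohort(n=50, n_variants=10)
        with pytest.raises(ValueError):
            es.genetic_scan(pheno.iloc[::-1], cov, gm)


def test_genomic_pcs_shape_and_orthogonality():
    dos, _ = ss.simulate_genotypes(80, 40, seed=3)
    pcs = es.genomic_principal_components(dos, 5)
    assert pcs.shape == (80, 5)
    gram = pcs.values.T @ pcs.values
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-6 * np.abs(np.diag(gram)).max()


def test_dosage_bounds_validated():
    dos = pd.DataFrame({"v1": [0.0, 2.5]}, index=["a", "b"])
    with pytest.raises(ValueError):
        es.GenotypeMatrix(dosages=dos, info=pd.Series({"v1": 1.0}))
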