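import numpy as np
import pandas as pd
import pytest

from alcomediome import diversity
from alcomediome.errors import DomainError, UsageError


def brute_force_bray_curtis(x, y):
    return np.sum(np.abs(x - y)) / np.sum(x + y)


def brute_force_pseudo_f(d, groups):
    """One-factor PERMANOVA pseudo-F from the between/within decomposition."""
    n = len(groups)
    d2 = d**2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    labels, counts = np.unique(groups, return_counts=True)
    for lab, cnt in zip(labels, counts):
        idx = np.flatnonzero(groups == lab)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(cnt, 1)].sum() / cnt
    ss_between = ss_total - ss_within
    k = len(labels)
    return (ss_between / (k - 1)) / (ss_within / (n - k))


class TestAlphaDiversity:
    def test_uniform_ten_species(self):
        a = diversity.alpha_diversity(np.full(10, 0.1))
        assert a.shannon == pytest.approx(np.log(10), abs=1e-12)
        assert a.inv_simpson == pytest.approx(10.0, abs=1e-12)
        assert a.richness == 10

    def test_single_species(self):
        a = diversity.alpha_diversity([5.0, 0.0, 0.0])
        assert a.shannon == 0.0
        assert a.inv_simpson == pytest.approx(1.0)
        assert a.richness == 1

    def test_hand_computed(self):
        a = diversity.alpha_diversity([0.5, 0.25, 0.25])
        assert a.shannon == pytest.approx(1.5 * np.log(2), abs=1e-12)
        assert a.inv_simpson == pytest.approx(1 / 0.375, abs=1e-12)

    def test_rescaling_invariance(self, rng):
        x = rng.random(30)
        a = diversity.alpha_diversity(x)
        b = diversity.alpha_diversity(x * 1234.5)
        assert a.shannon == pytest.approx(b.shannon, abs=1e-12)
        assert a.inv_simpson == pytest.approx(b.inv_simpson, abs=1e-12)

    def test_all_zero_error(self):
        with pytest.raises(DomainError):
            diversity.alpha_diversity([0.0, 0.0])

    def test_invariants(self, rng):
        for _ in range(20):
            x = rng.random(25) * (rng.random(25) > 0.3)
            if x.sum() == 0:
                continue
            a = diversity.alpha_diversity(x)
            assert 1 <= a.inv_simpson <= a.richness + 1e-12
            assert 0 <= a.shannon <= np.log(a.richness) + 1e-12

    def test_log_base_flag(self):
        a = diversity.alpha_diversity(np.full(8, 1.0), log_base=2)
        assert a.shannon == pytest.approx(3.0, abs=1e-12)


class TestAlphaRegression:
    def test_recovery_of_known_shift(self, rng):
        n = 2000
        consumer = rng.random(n) < 0.8
        age = rng.uniform(55, 77, n)
        ln_index = 1.0 + np.log(1.027) * consumer + 0.001 * age + rng.normal(0, 0.05, n)
        df = pd.DataFrame({"consumer": consumer, "age": age})
        res = diversity.alpha_regression(pd.Series(np.exp(ln_index)), df, "consumer", ["age"])
        row = res.iloc[0]
        assert row["ci_low"] <= 2.7 <= row["ci_high"]
        assert row["pct_diff"] == pytest.approx(2.7, abs=1.0)

    def test_null_calibration(self, rng):
        n = 150
        rejections = 0
        n_sims = 200
        for _ in range(n_sims):
            exposurev = rng.random(n)
            ln_index = rng.normal(1.0, 0.2, n)
            df = pd.DataFrame({"x": exposurev})
            res = diversity.alpha_regression(pd.Series(np.exp(ln_index)), df, "x")
            rejections += res["p"].iloc[0] < 0.05
        assert 0.01 <= rejections / n_sims <= 0.11

    def test_nonpositive_index_error(self):
        df = pd.DataFrame({"x": [0.1, 0.2]})
        with pytest.raises(DomainError):
            diversity.alpha_regression(pd.Series([1.0, 0.0]), df, "x")

    def test_orthogonal_exposure_residual_variance(self, rng):
        import statsmodels.api as sm

        n = 300
        cov = rng.normal(size=n)
        # exposure orthogonal to covariate and intercept by construction
        raw = rng.normal(size=n)
        X = np.column_stack([np.ones(n), cov])
        expo = raw - X @ np.linalg.lstsq(X, raw, rcond=None)[0]
        y = 2.0 + 0.5 * cov + rng.normal(0, 0.1, n)
        r_cov = sm.OLS(y, X).fit().params
        full = sm.OLS(y, np.column_stack([X, expo])).fit()
        # covariate coefficients unchanged by an orthogonal exposure
        np.testing.assert_allclose(full.params[:2], r_cov, atol=1e-10)


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]] * 2, index=["a", "b"])
        assert diversity.bray_curtis(m).values[0, 1] == pytest.approx(0.0, abs=1e-15)

    def test_disjoint_supports_one(self):
        m = pd.DataFrame([[1.0, 0.0], [0.0, 5.0]], index=["a", "b"])
        assert diversity.bray_curtis(m).values[0, 1] == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        m = pd.DataFrame([[6.0, 2.0], [2.0, 2.0]], index=["a", "b"])
        assert diversity.bray_curtis(m).values[0, 1] == pytest.approx(1 / 3, abs=1e-12)

    def test_double_loop_oracle(self, rng):
        m = pd.DataFrame(rng.random((10, 10)))
        dm = diversity.bray_curtis(m)
        x = m.to_numpy()
        for i in range(10):
            for j in range(10):
                expected = 0.0 if i == j else brute_force_bray_curtis(x[i], x[j])
                assert dm.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_sample_named_in_error(self):
        m = pd.DataFrame([[1.0, 1.0], [0.0, 0.0]], index=["ok", "empty"])
        with pytest.raises(DomainError, match="empty"):
            diversity.bray_curtis(m)


class TestPcoa:
    def test_planar_points_recovered(self, rng):
        from scipy.spatial.distance import pdist, squareform
        from scipy.spatial import procrustes

        pts = rng.normal(size=(15, 2))
        dm = diversity.DistanceMatrix(tuple(range(15)), squareform(pdist(pts)))
        coords, eigvals = diversity.pcoa(dm, k=2)
        _, _, disparity = procrustes(pts - pts.mean(0), coords)
        assert disparity < 1e-8

    def test_identical_samples_identical_coords(self):
        m = pd.DataFrame([[1, 2.0], [1, 2.0], [3, 1.0]], index=list("abc"))
        dm = diversity.bray_curtis(m)
        coords, _ = diversity.pcoa(dm, k=2)
        np.testing.assert_allclose(coords[0], coords[1], atol=1e-8)

    def test_eigenvalue_sum_equals_trace(self, rng):
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(rng.random((12, 6))))
        dm = diversity.DistanceMatrix(tuple(range(12)), d)
        _, eigvals = diversity.pcoa(dm, k=3)
        g = diversity._gower_center(d)
        assert eigvals.sum() == pytest.approx(np.trace(g), abs=1e-8)

    def test_k_too_large(self):
        m = pd.DataFrame(np.eye(3) + 0.1, index=list("abc"))
        with pytest.raises(UsageError):
            diversity.pcoa(diversity.bray_curtis(m), k=3)


class TestPermanova:
    def _random_dm(self, rng, n=30, p=8):
        from scipy.spatial.distance import pdist, squareform

        x = rng.random((n, p))
        return diversity.DistanceMatrix(tuple(range(n)), squareform(pdist(x, "braycurtis")))

    def test_one_factor_matches_brute_force(self, rng):
        for _ in range(5):
            dm = self._random_dm(rng)
            groups = rng.choice(["a", "b", "c"], size=dm.n)
            if len(np.unique(groups)) < 3:
                continue
            design = pd.DataFrame({"g": groups})
            res = diversity.permanova(dm, design, "g", n_perm=19, seed=1)
            expected = brute_force_pseudo_f(dm.values, groups)
            assert res.pseudo_f == pytest.approx(expected, abs=1e-10)

    def test_p_value_lower_bound(self, rng):
        dm = self._random_dm(rng)
        design = pd.DataFrame({"g": rng.choice(["a", "b"], size=dm.n)})
        res = diversity.permanova(dm, design, "g", n_perm=99, seed=5)
        assert 1 / 100 <= res.p_perm <= 1.0

    def test_null_omega_squared_near_zero(self, rng):
        omegas = []
        for _ in range(60):
            dm = self._random_dm(rng, n=40)
            design = pd.DataFrame({"g": rng.choice(["a", "b"], size=dm.n)})
            res = diversity.permanova(dm, design, "g", n_perm=19, seed=3)
            omegas.append(res.omega_sq)
        assert abs(np.mean(omegas)) < 0.005

    def test_detects_real_structure_with_covariate(self, rng):
        from scipy.spatial.distance import pdist, squareform

        n = 80
        g = rng.random(n) < 0.5
        age = rng.uniform(55, 77, n)
        x = rng.random((n, 10)) + 0.4 * g[:, None]
        dm = diversity.DistanceMatrix(tuple(range(n)), squareform(pdist(x, "braycurtis")))
        design = pd.DataFrame({"g": g, "age": age})
        res = diversity.permanova(dm, design, "g", covariates=["age"], n_perm=199, seed=2)
        assert res.p_perm <= 0.01
        assert res.omega_sq > 0.05

    def test_seed_required(self, rng):
        dm = self._random_dm(rng)
        with pytest.raises(UsageError):
            diversity.permanova(dm, pd.DataFrame({"g": ["a", "b"] * 15}), "g")

    def test_aliased_term_error(self, rng):
        from alcomediome.errors import RankError

        dm = self._random_dm(rng)
        g = rng.choice(["a", "b"], size=dm.n)
        design = pd.DataFrame({"g": g, "g2": g})
        with pytest.raises(RankError):
            diversity.permanova(dm, design, "g2", covariates=["g"], n_perm=9, seed=1)


class TestDispersion:
    def test_identical_group_zero_median(self, rng):
        x = np.vstack([np.tile([1.0, 2.0, 3.0], (4, 1)), rng.random((4, 3)) + 1])
        m = pd.DataFrame(x, index=[f"s{i}" for i in range(8)])
        dm = diversity.bray_curtis(m)
        groups = ["same"] * 4 + ["vary"] * 4
        res = diversity.dispersion(dm, groups, reference="same", n_perm=99, seed=1)
        assert res.loc[res["group"] == "same", "median_dist"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_tighter_group_detected(self, rng):
        from scipy.spatial.distance import pdist, squareform

        n = 200
        tight = rng.normal(0, 0.05, (n // 2, 5)) + 1.0
        loose = rng.normal(0, 0.6, (n // 2, 5)) + 1.0
        x = np.abs(np.vstack([tight, loose]))
        dm = diversity.DistanceMatrix(tuple(range(n)), squareform(pdist(x, "braycurtis")))
        groups = ["tight"] * (n // 2) + ["loose"] * (n // 2)
        res = diversity.dispersion(dm, groups, reference="tight", n_perm=199, seed=2)
        med = res.set_index("group")["median_dist"]
        assert med["tight"] < med["loose"]
        assert res.set_index("group").loc["loose", "p_perm"] < 0.05

    def test_null_calibration(self, rng):
        from scipy.spatial.distance import pdist, squareform

        pvals = []
        for _ in range(100):
            x = rng.random((30, 5))
            dm = diversity.DistanceMatrix(tuple(range(30)), squareform(pdist(x, "braycurtis")))
            groups = ["a"] * 15 + ["b"] * 15
            res = diversity.dispersion(dm, groups, reference="a", n_perm=49, seed=4)
            pvals.append(res["p_perm"].dropna().iloc[0])
        assert 0.01 <= np.mean(np.array(pvals) < 0.05) <= 0.12

    def test_singleton_group_error(self, rng):
        m = pd.DataFrame(rng.random((5, 3)), index=list("abcde"))
        dm = diversity.bray_curtis(m)
        with pytest.raises(UsageError):
            diversity.dispersion(dm, ["x", "x", "x", "x", "y"], n_perm=9, seed=1)
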