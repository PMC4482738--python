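"""Soil PCA, CCA, Mantel and dispersion-gradient regression."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from phyloassembly.data_model import DistanceMatrix
from phyloassembly.gradient_stats import (cca, cca_axis_test, mantel,
                                          regress_ses_on_axis, soil_distance,
                                          soil_pca)


class TestSoilPCA:
    def test_perfectly_correlated_pair(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        soil = pd.DataFrame({"a": x, "b": 2 * x + 5})
        res = soil_pca(soil)
        assert res.explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_independent_variables_near_equal_fractions(self):
        rng = np.random.default_rng(1)
        soil = pd.DataFrame(rng.normal(size=(4000, 3)), columns=list("abc"))
        res = soil_pca(soil)
        assert np.all(np.abs(res.explained - 1 / 3) < 0.05)

    def test_eigenvalues_match_characteristic_polynomial(self):
        rng = np.random.default_rng(2)
        soil = pd.DataFrame(rng.normal(size=(5, 4)), columns=list("abcd"))
        res = soil_pca(soil)
        z = (soil - soil.mean()) / soil.std(ddof=1)
        corr = np.corrcoef(z.to_numpy(), rowvar=False)
        # oracle: roots of det(C - lambda I)
        roots = np.sort(np.real(np.roots(np.poly(corr))))[::-1]
        lam = res.explained * res.total
        assert np.allclose(np.sort(lam)[::-1], np.maximum(roots, 0), atol=1e-8)

    def test_scores_uncorrelated_and_total_is_nvars(self):
        rng = np.random.default_rng(3)
        soil = pd.DataFrame(rng.normal(size=(40, 5)),
                            columns=list("abcde"))
        res = soil_pca(soil)
        cov = np.cov(res.scores.to_numpy(), rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.all(np.abs(off) < 1e-9)
        assert res.total == pytest.approx(5.0)

    def test_zero_variance_column_named(self):
        soil = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="flat"):
            soil_pca(soil)


def brute_cca_eigs(y, x):
    """Independent CCA oracle: regress each chi-square-standardized column
    on the weighted env and eigendecompose the fitted cross-product."""
    y = np.asarray(y, float)
    total = y.sum()
    p = y / total
    r, c = p.sum(1), p.sum(0)
    qbar = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    xw = (x - r @ x)
    xw = xw / np.sqrt(r @ xw ** 2)
    z = np.sqrt(r)[:, None] * xw
    fitted = np.empty_like(qbar)
    for j in range(qbar.shape[1]):
        beta, *_ = np.linalg.lstsq(z, qbar[:, j], rcond=None)
        fitted[:, j] = z @ beta
    lam = np.linalg.eigvalsh(fitted @ fitted.T)[::-1]
    return lam[lam > 1e-12], (qbar ** 2).sum()


class TestCCA:
    def setup_method(self):
        self.y = np.array([[5, 2, 0, 1], [0, 3, 4, 1], [2, 0, 3, 5],
                           [4, 4, 1, 0], [1, 0, 5, 2], [0, 5, 2, 3]], float)
        self.env = pd.DataFrame({"e1": [0.2, 1.4, -0.5, 0.9, -1.2, 0.1],
                                 "e2": [2.0, 1.0, 0.5, -0.3, 0.8, -1.5]})

    def test_reference_eigenvalues(self):
        # frozen from an independent implementation (vegan::cca) in-session
        res = cca(self.y, self.env)
        eig = res.explained * res.total
        assert eig[0] == pytest.approx(0.1781272, abs=1e-6)
        assert eig[1] == pytest.approx(0.07829651, abs=1e-7)
        assert res.total == pytest.approx(0.6555159, abs=1e-6)

    def test_matches_bruteforce_oracle(self):
        eig_o, total_o = brute_cca_eigs(self.y, self.env.to_numpy())
        res = cca(self.y, self.env)
        assert np.allclose(res.explained * res.total, eig_o[:2], atol=1e-9)
        assert res.total == pytest.approx(total_o, abs=1e-12)

    def test_total_inertia_is_scaled_chi_square(self):
        from scipy.stats import chi2_contingency
        res = cca(self.y, self.env)
        chi2 = chi2_contingency(self.y, correction=False)[0]
        assert res.total == pytest.approx(chi2 / self.y.sum(), rel=1e-12)

    def test_binary_split_captured_by_axis_one(self):
        # two disjoint species blocks perfectly separated by one env variable
        rng = np.random.default_rng(11)
        block1 = rng.poisson(5.0, size=(5, 3)) + 1
        block2 = rng.poisson(5.0, size=(5, 3)) + 1
        y = np.zeros((10, 6))
        y[:5, :3] = block1
        y[5:, 3:] = block2
        env = pd.DataFrame({"e": [0.0] * 5 + [1.0] * 5})
        res = cca(y, env)
        # axis 1 carries the whole between-block inertia
        between = brute_cca_eigs(y, env.to_numpy())[0][0]
        assert res.explained[0] * res.total == pytest.approx(between, rel=1e-9)
        p = cca_axis_test(y, env, n_perm=199, seed=1)
        assert p[0] <= 0.05  # block structure is as extreme as it gets

    def test_collinear_env_rejected(self):
        env = self.env.assign(e3=lambda d: 2 * d["e1"] - d["e2"])
        with pytest.raises(ValueError, match="collinear"):
            cca(self.y, env)

    def test_axis_test_null_pvalues_not_extreme(self):
        rng = np.random.default_rng(4)
        y = rng.poisson(3.0, size=(10, 8)).astype(float) + 1
        env = pd.DataFrame({"e1": rng.normal(size=10), "e2": rng.normal(size=10)})
        ps = [cca_axis_test(y, env, n_perm=99, seed=s)[0] for s in range(20)]
        # unrelated env: p should behave like a uniform draw, not pile at 0.01
        assert np.mean(np.array(ps) <= 0.05) <= 0.3
        assert np.mean(ps) > 0.2

    def test_permutation_reproducible(self):
        a = cca_axis_test(self.y, self.env, n_perm=99, seed=7)
        b = cca_axis_test(self.y, self.env, n_perm=99, seed=7)
        assert np.array_equal(a, b)


class TestMantel:
    def _dm(self, m, labels=None):
        labels = labels or [str(i) for i in range(len(m))]
        return DistanceMatrix(labels, m)

    def test_identical_matrices_r_one(self):
        rng = np.random.default_rng(5)
        m = squareform(pdist(rng.normal(size=(6, 2))))
        res = mantel(self._dm(m), self._dm(m), n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100, abs=0.03)

    def test_affine_transform_r_one(self):
        rng = np.random.default_rng(6)
        m = squareform(pdist(rng.normal(size=(6, 2))))
        m2 = 3.0 * m + squareform(np.full(15, 2.0))
        res = mantel(self._dm(m), self._dm(m2), n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_p_matches_exhaustive_enumeration_four_units(self):
        rng = np.random.default_rng(7)
        m1 = squareform(pdist(rng.normal(size=(4, 2))))
        m2 = squareform(pdist(rng.normal(size=(4, 2))))
        iu = np.triu_indices(4, 1)
        a = m1[iu]
        r_obs = np.corrcoef(a, m2[iu])[0, 1]
        count = 0
        n_all = 0
        for perm in itertools.permutations(range(4)):
            b = m2[np.ix_(perm, perm)][iu]
            count += np.corrcoef(a, b)[0, 1] >= r_obs - 1e-12
            n_all += 1
        exact_exceed_frac = count / n_all  # 24 permutations
        res = mantel(self._dm(m1), self._dm(m2), n_perm=20000, seed=1)
        mc_exceed = (res.p_value * (20000 + 1) - 1) / 20000
        assert mc_exceed == pytest.approx(exact_exceed_frac, abs=0.02)

    def test_label_mismatch_and_small_n_rejected(self):
        m = squareform(pdist(np.random.default_rng(8).normal(size=(4, 2))))
        with pytest.raises(ValueError, match="labels"):
            mantel(self._dm(m), self._dm(m, labels=list("wxyz")), n_perm=9)
        m2 = m[:2, :2]
        with pytest.raises(ValueError, match=">= 3"):
            mantel(self._dm(m2), self._dm(m2), n_perm=9)


class TestRegression:
    def test_exact_linear_relation(self):
        scores = np.array([-1.0, 0.0, 1.0, 2.0])
        fit = regress_ses_on_axis(2 * scores, scores)
        assert fit.slope == pytest.approx(2.0)
        assert fit.r == pytest.approx(1.0)

    def test_three_point_closed_form(self):
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([1.0, 3.0, 4.0])
        fit = regress_ses_on_axis(y, x)
        assert fit.slope == pytest.approx(1.5)
        assert fit.intercept == pytest.approx(7 / 6)

    def test_independent_noise_p_uniformish(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(500):
            ps.append(regress_ses_on_axis(rng.normal(size=12),
                                          rng.normal(size=12)).p_value)
        assert np.mean(ps) == pytest.approx(0.5, abs=0.06)
        assert np.mean(np.array(ps) < 0.05) == pytest.approx(0.05, abs=0.03)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            regress_ses_on_axis([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])


def test_soil_distance_is_euclidean_on_zscores():
    rng = np.random.default_rng(10)
    soil = pd.DataFrame(rng.normal(size=(5, 3)), columns=list("abc"),
                        index=[f"P{i}" for i in range(5)])
    d = soil_distance(soil)
    z = (soil - soil.mean()) / soil.std(ddof=1)
    assert np.allclose(d.values, squareform(pdist(z.to_numpy())), atol=1e-12)
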