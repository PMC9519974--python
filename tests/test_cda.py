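"""Canonical discriminant analysis against brute-force eigen oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from psycop.cda import cda_groups, cda_terms, data_ellipse
from psycop.stats import factorial_ssp, encode_design


def _toy_two_groups():
    # 6 points, 2 variables, 2 groups
    X = pd.DataFrame(
        [[0.0, 0.1], [0.4, -0.2], [0.1, 0.3],
         [2.0, 1.1], [2.3, 0.8], [1.8, 1.4]],
        columns=["v1", "v2"], index=[f"m{i}" for i in range(6)])
    g = pd.Series(["a", "a", "a", "b", "b", "b"], index=X.index)
    return X, g


def _scatter(X, g):
    W = np.zeros((X.shape[1],) * 2)
    B = np.zeros_like(W)
    grand = X.mean(axis=0).to_numpy()
    for lab in g.unique():
        sub = X[g == lab].to_numpy()
        d = sub - sub.mean(axis=0)
        W += d.T @ d
        B += len(sub) * np.outer(sub.mean(axis=0) - grand, sub.mean(axis=0) - grand)
    return B, W


class TestCdaGroups:
    def test_eigenvalues_match_brute_force(self):
        X, g = _toy_two_groups()
        B, W = _scatter(X, g)
        ref = np.linalg.eigvals(np.linalg.inv(W) @ B)
        ref = np.sort(np.real(ref))[::-1]
        res = cda_groups(X, g)
        assert res.eigenvalues[0] == pytest.approx(ref[0], rel=1e-10)

    def test_coefficients_solve_generalized_eigenproblem(self):
        X, g = _toy_two_groups()
        B, W = _scatter(X, g)
        res = cda_groups(X, g)
        v = res.raw_coef.to_numpy()[:, 0]
        lam = res.eigenvalues[0]
        assert np.allclose(B @ v, lam * (W @ v), atol=1e-8)

    def test_scores_are_centered_data_times_coefficients(self):
        X, g = _toy_two_groups()
        res = cda_groups(X, g)
        expected = (X - X.mean(axis=0)).to_numpy() @ res.raw_coef.to_numpy()
        assert np.allclose(res.scores.to_numpy(), expected)

    def test_within_group_score_variance_is_unit(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("xyz"))
        g = pd.Series(rng.choice(["a", "b", "c", "d"], size=40), index=X.index)
        res = cda_groups(X, g)
        sc = res.scores.to_numpy()
        W = np.zeros((sc.shape[1],) * 2)
        for lab in g.unique():
            d = sc[(g == lab).to_numpy()]
            d = d - d.mean(axis=0)
            W += d.T @ d
        assert np.allclose(W / (40 - g.nunique()), np.eye(sc.shape[1]), atol=1e-8)

    def test_identical_group_means_give_zero_eigenvalues(self):
        X0 = pd.DataFrame([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.5], [0.5, -0.5]],
                          columns=["v1", "v2"])
        X = pd.concat([X0, X0], ignore_index=True)
        X.index = [f"m{i}" for i in range(8)]
        g = pd.Series(["a"] * 4 + ["b"] * 4, index=X.index)
        res = cda_groups(X, g)
        assert np.all(res.eigenvalues < 1e-10)

    def test_affine_rescaling_leaves_canonical_correlations(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("xyz"))
        g = pd.Series(rng.choice(["a", "b"], size=30), index=X.index)
        res1 = cda_groups(X, g)
        X2 = X.copy()
        X2["y"] = X2["y"] * 7.5 - 3.0
        res2 = cda_groups(X2, g)
        assert np.allclose(res1.canonical_correlations,
                           res2.canonical_correlations, atol=1e-8)

    def test_percents_sum_to_100(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 4)))
        X.index = [f"m{i}" for i in range(40)]
        g = pd.Series(rng.choice(list("abcd"), size=40), index=X.index)
        res = cda_groups(X, g)
        assert res.percents.sum() == pytest.approx(100.0)

    def test_incomplete_matrix_rejected(self):
        X, g = _toy_two_groups()
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            cda_groups(X, g)


class TestCdaTerms:
    def _design(self, n_per_cell=8):
        rows = []
        for s in ("placebo", "spironolactone"):
            for a in ("placebo", "aripiprazole"):
                rows += [{"S": s, "A": a}] * n_per_cell
        d = pd.DataFrame(rows)
        d.index = [f"m{i}" for i in range(len(d))]
        return d

    def test_single_variable_eigenvalue_is_ssh_over_sse(self, rng):
        d = self._design()
        X = pd.DataFrame({"y": rng.normal(size=len(d))}, index=d.index)
        res = cda_terms(X, d)
        xs, xa = encode_design(d)
        H, E, _ = factorial_ssp(X.to_numpy(), xs, xa)
        for term in ("S", "A", "SxA"):
            assert res[term].eigenvalues[0] == pytest.approx(
                H[term][0, 0] / E[0, 0], rel=1e-8)

    def test_balanced_scatter_decomposition(self, rng):
        """In a balanced design term H matrices plus E recover the total scatter."""
        d = self._design()
        X = pd.DataFrame(rng.normal(size=(len(d), 3)), index=d.index,
                         columns=list("xyz"))
        xs, xa = encode_design(d)
        H, E, _ = factorial_ssp(X.to_numpy(), xs, xa)
        Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
        total = Xc.T @ Xc
        assert np.allclose(H["S"] + H["A"] + H["SxA"] + E, total, atol=1e-8)

    def test_effect_on_single_variable_dominates_its_term(self, rng):
        """An S-only shift on one variable puts the top S-term weight there."""
        d = self._design(10)
        X = pd.DataFrame(rng.normal(size=(len(d), 4)), index=d.index,
                         columns=["a", "b", "c", "d"])
        X.loc[d["S"] == "spironolactone", "c"] += 3.0
        res = cda_terms(X, d)
        coefs = res["S"].std_coef.iloc[:, 0].abs()
        assert coefs.idxmax() == "c"
        # and the interaction term stays near the null
        assert res["SxA"].eigenvalues[0] < res["S"].eigenvalues[0] / 5

    def test_simple_effect_cdas_present(self, rng):
        d = self._design(8)
        X = pd.DataFrame(rng.normal(size=(len(d), 3)), index=d.index,
                         columns=list("xyz"))
        res = cda_terms(X, d)
        assert {"S", "A", "SxA", "P-S", "A-S"} <= set(res)


class TestDataEllipse:
    def test_isotropic_unit_variance_radius(self, rng):
        pts = rng.normal(size=(500, 2))
        # whiten exactly so the sample covariance is the identity
        pts = pts - pts.mean(axis=0)
        L = np.linalg.cholesky(np.cov(pts, rowvar=False))
        pts = pts @ np.linalg.inv(L).T
        ell = data_ellipse(pts, coverage=0.75)
        r = np.sqrt(sps.chi2.ppf(0.75, 2))
        assert ell.semi_axes[0] == pytest.approx(r, rel=1e-6)
        assert ell.semi_axes[1] == pytest.approx(r, rel=1e-6)
        assert r == pytest.approx(1.6651, abs=1e-4)

    def test_coverage_to_zero_shrinks_axes(self, rng):
        pts = rng.normal(size=(50, 2))
        big = data_ellipse(pts, coverage=0.75)
        small = data_ellipse(pts, coverage=1e-6)
        assert small.semi_axes[0] < big.semi_axes[0] * 1e-2

    def test_rotation_equivariance(self, rng):
        pts = rng.normal(size=(60, 2)) @ np.diag([3.0, 1.0])
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        e1 = data_ellipse(pts)
        e2 = data_ellipse(pts @ R.T)
        d = (e2.angle - e1.angle - theta) % np.pi
        assert min(d, np.pi - d) == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(e1.semi_axes, e2.semi_axes)

    def test_degenerate_covariance_rejected(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError, match="degenerate"):
            data_ellipse(pts)
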