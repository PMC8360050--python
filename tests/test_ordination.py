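"""Tests of log-ratio PCA, RDA, CCA and the permutation test."""

import shutil
import subprocess
import textwrap

import numpy as np
import pytest

from sparseclr import (cca, double_center, double_centered_log, clr, lr_pca,
                       permutation_test, rda)


class TestLrPca:
    def test_two_by_two_by_hand(self):
        res = lr_pca(np.array([[-1.0, 1.0], [1.0, -1.0]]), K=1)
        assert res.singular_values[0] == pytest.approx(2.0)
        np.testing.assert_allclose(res.explained_fraction, [1.0])
        # loadings are (1, -1)/sqrt(2) up to sign
        np.testing.assert_allclose(np.abs(res.taxon_loadings[:, 0]),
                                   1 / np.sqrt(2))

    def test_zero_matrix(self):
        res = lr_pca(np.zeros((3, 4)))
        np.testing.assert_allclose(res.singular_values, 0.0)

    def test_frobenius_conservation(self, rng):
        S = double_center(rng.normal(size=(6, 9))).S
        res = lr_pca(S)
        assert (res.singular_values ** 2).sum() == pytest.approx((S ** 2).sum())
        assert res.explained_fraction.sum() == pytest.approx(1.0)

    def test_orthonormal_axes_and_reconstruction(self, rng):
        S = double_center(rng.normal(size=(5, 7))).S
        res = lr_pca(S)
        U, V, s = res.sample_scores, res.taxon_loadings, res.singular_values
        np.testing.assert_allclose(U.T @ U, np.eye(res.K), atol=1e-10)
        np.testing.assert_allclose(V.T @ V, np.eye(res.K), atol=1e-10)
        np.testing.assert_allclose(U @ np.diag(s) @ V.T, S, atol=1e-8)

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError, match="rank"):
            lr_pca(np.zeros((4, 6)), K=4)

    def test_equals_pca_of_column_centred_clr(self, example_draws):
        Y, _ = example_draws[1.0]
        s1 = lr_pca(double_centered_log(Y)).singular_values
        C = clr(Y)
        C = C - C.mean(axis=0)
        s2 = np.linalg.svd(C, compute_uv=False)[: len(s1)]
        np.testing.assert_allclose(s1, s2, atol=1e-8)


def brute_force_between_fraction(M, x):
    """Between-group variance over total variance, by explicit group means."""
    M = np.asarray(M, float)
    fit = np.zeros_like(M)
    for g in np.unique(x):
        idx = x == g
        fit[idx] = M[idx].mean(axis=0)
    fit -= M.mean(axis=0)
    Mc = M - M.mean(axis=0)
    return (fit ** 2).sum() / (Mc ** 2).sum()


class TestRda:
    def test_full_recovery_on_contrast(self):
        res = rda(np.array([[-1.0, 1.0], [1.0, -1.0]]), np.array([0.0, 1.0]))
        assert res.constrained_fraction == pytest.approx(1.0)

    def test_orthogonal_x_gives_zero(self):
        M = np.array([[-1.0, 1.0], [1.0, -1.0], [0.0, 0.0]])
        x = np.array([1.0, 1.0, -2.0])  # centred x orthogonal to M's columns
        assert rda(M, x).constrained_fraction == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_group_decomposition(self, rng):
        M = rng.normal(size=(4, 3))
        M -= M.mean(axis=0)
        x = np.array([0, 0, 1, 1], float)
        assert rda(M, x).constrained_fraction == pytest.approx(
            brute_force_between_fraction(M, x))

    def test_monotone_in_design_columns(self, rng):
        M = double_center(rng.normal(size=(8, 5))).S
        x1 = rng.normal(size=(8, 1))
        x2 = np.hstack([x1, rng.normal(size=(8, 1))])
        f1 = rda(M, x1).constrained_fraction
        f2 = rda(M, x2).constrained_fraction
        assert 0 <= f1 <= f2 <= 1

    def test_constant_x_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            rda(rng.normal(size=(4, 3)), np.ones(4))


class TestCca:
    @staticmethod
    def _oracle(Y, x):
        """Weighted-regression CA oracle built column-by-column."""
        Y = np.asarray(Y, float)
        P = Y / Y.sum()
        wr, wc = P.sum(1), P.sum(0)
        Q = (P - np.outer(wr, wc)) / np.sqrt(np.outer(wr, wc))
        xc = x - (wr * x).sum()
        z = np.sqrt(wr) * xc
        fit = np.zeros_like(Q)
        for j in range(Q.shape[1]):
            beta = (z @ Q[:, j]) / (z @ z)
            fit[:, j] = z * beta
        return (fit ** 2).sum() / (Q ** 2).sum()

    def test_matches_weighted_regression_oracle(self, rng):
        Y = rng.integers(1, 20, size=(3, 3))
        x = np.array([0.0, 1.0, 1.0])
        assert cca(Y, x).constrained_fraction == pytest.approx(
            self._oracle(Y, x))

    def test_saturated_design_explains_everything(self, rng):
        Y = rng.integers(1, 20, size=(4, 6))
        dummies = np.eye(4)
        assert cca(Y, dummies).constrained_fraction == pytest.approx(1.0)

    def test_constant_x_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            cca(rng.integers(1, 5, size=(3, 3)), np.ones(3))

    def test_zero_margin_rejected(self):
        Y = np.array([[0, 0], [1, 2]])
        with pytest.raises(ValueError):
            cca(Y, np.array([0.0, 1.0]))


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
class TestAgainstVegan:
    """Independent oracle: vegan's rda/cca constrained inertia fractions."""

    def _run_r(self, script, tmp_path):
        path = tmp_path / "check.R"
        path.write_text(script)
        out = subprocess.run(["Rscript", "--vanilla", str(path)],
                             capture_output=True, text=True, cwd=tmp_path)
        assert out.returncode == 0, out.stderr
        return float(out.stdout.strip().split()[-1])

    def test_rda_fraction_matches_vegan(self, rng, tmp_path):
        M = double_center(rng.normal(size=(8, 5))).S
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1], float)
        np.savetxt(tmp_path / "M.txt", M)
        np.savetxt(tmp_path / "x.txt", x)
        frac = self._run_r(textwrap.dedent("""
            suppressMessages(library(vegan))
            M <- as.matrix(read.table("M.txt")); x <- scan("x.txt", quiet=TRUE)
            m <- rda(M ~ x)
            cat(sprintf("%.15f", m$CCA$tot.chi / m$tot.chi), "\\n")
        """), tmp_path)
        assert rda(M, x).constrained_fraction == pytest.approx(frac, abs=1e-8)

    def test_cca_fraction_matches_vegan(self, rng, tmp_path):
        Y = rng.integers(1, 30, size=(7, 5))
        x = np.array([0, 1, 0, 1, 0, 1, 0], float)
        np.savetxt(tmp_path / "Y.txt", Y, fmt="%d")
        np.savetxt(tmp_path / "x.txt", x)
        frac = self._run_r(textwrap.dedent("""
            suppressMessages(library(vegan))
            Y <- as.matrix(read.table("Y.txt")); x <- scan("x.txt", quiet=TRUE)
            m <- cca(Y ~ x)
            cat(sprintf("%.15f", m$CCA$tot.chi / m$tot.chi), "\\n")
        """), tmp_path)
        assert cca(Y, x).constrained_fraction == pytest.approx(frac, abs=1e-8)


class TestPermutationTest:
    def test_invariant_statistic_gives_p_one(self, rng):
        # with 2 samples every permutation reproduces the same contrast
        S = np.array([[-1.0, 1.0], [1.0, -1.0]])
        res = permutation_test(S, np.array([0.0, 1.0]), n_perm=19, rng=rng)
        assert res.p_value == 1.0

    def test_p_value_formula_invariant(self, rng, example_draws):
        Y, draw = example_draws[0.5]
        S = double_centered_log(Y)
        res = permutation_test(S.S, draw.x.astype(float), n_perm=99, rng=rng)
        n_ge = (res.perm_stats >= res.constrained_fraction - 1e-12).sum()
        assert res.p_value == pytest.approx((1 + n_ge) / 100)
        assert 0 < res.p_value <= 1

    def test_observed_statistic_matches_rda(self, rng, example_draws):
        Y, draw = example_draws[0.0]
        S = double_centered_log(Y)
        res = permutation_test(S.S, draw.x.astype(float), n_perm=9, rng=rng)
        assert res.constrained_fraction == pytest.approx(
            rda(S.S, draw.x.astype(float)).constrained_fraction, abs=1e-10)

    def test_cca_route_agrees_with_loop(self, rng):
        Y = rng.integers(0, 12, size=(10, 8)) + (rng.random((10, 8)) < 0.7)
        Y = np.asarray(Y, int)
        Y[Y.sum(axis=1) == 0, 0] = 1
        keep = Y.sum(axis=0) > 0
        Y = Y[:, keep]
        x = np.array([0, 1] * 5, float)
        res = permutation_test(Y, x, n_perm=49, rng=rng, method="cca")
        assert res.constrained_fraction == pytest.approx(
            cca(Y, x).constrained_fraction, abs=1e-10)
        assert 0 < res.p_value <= 1

    def test_null_p_values_super_uniform(self, rng):
        # exchangeable null: rejection at alpha=0.2 within binomial noise
        hits = 0
        n_sims = 150
        for _ in range(n_sims):
            M = double_center(rng.normal(size=(12, 6))).S
            x = np.array([0, 1] * 6, float)
            x = x[rng.permutation(12)]
            hits += permutation_test(M, x, n_perm=39, rng=rng).p_value <= 0.2
        assert abs(hits / n_sims - 0.2) < 3 * np.sqrt(0.2 * 0.8 / n_sims)

    def test_bad_arguments(self, rng):
        with pytest.raises(ValueError):
            permutation_test(np.zeros((4, 3)), np.array([0, 1, 0, 1.0]),
                             n_perm=0, rng=rng)
        with pytest.raises(ValueError):
            permutation_test(np.eye(4), np.arange(4.0), rng=rng,
                             method="nope")
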