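"""Reconstruction metrics, factor PCA, DCI, MIG and resampling reports."""

import numpy as np
import pandas as pd
import pytest

from fundusvae import disentangle as dis


def naive_ssim(x, y, win=7, sigma=1.5, k1=0.01, k2=0.03):
    """From-scratch Gaussian-weighted SSIM (single channel), mean over pixels."""
    from scipy.ndimage import correlate

    half = win // 2
    radius = int(3.5 * sigma + 0.5)  # gaussian support; `win` only sets the crop
    ax = np.arange(-radius, radius + 1)
    g = np.exp(-(ax**2) / (2 * sigma**2))
    kernel = np.outer(g, g)
    kernel /= kernel.sum()

    def f(a):
        return correlate(a, kernel, mode="reflect")

    mx, my = f(x), f(y)
    vx = f(x * x) - mx**2
    vy = f(y * y) - my**2
    cxy = f(x * y) - mx * my
    c1, c2 = k1**2, k2**2
    s = ((2 * mx * my + c1) * (2 * cxy + c2)) / ((mx**2 + my**2 + c1) * (vx + vy + c2))
    return float(s[half:-half, half:-half].mean())


class TestSSIM:
    def test_identity(self):
        x = np.random.default_rng(0).random((24, 24, 3))
        assert dis.ssim(x, x) == pytest.approx(1.0)

    def test_inverted_image_scores_low(self):
        x = np.random.default_rng(1).random((32, 32))
        assert dis.ssim(x, 1.0 - x) < 0.5

    def test_matches_independent_implementation(self):
        rng = np.random.default_rng(2)
        x = rng.random((16, 16))
        y = np.clip(x + 0.1, 0, 1)
        assert dis.ssim(x, y) == pytest.approx(naive_ssim(x, y), abs=1e-6)
        assert dis.ssim(x, y) < 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.random((20, 20)), rng.random((20, 20))
        assert dis.ssim(x, y) == pytest.approx(dis.ssim(y, x), abs=1e-12)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            dis.ssim(np.zeros((5, 5)), np.zeros((5, 5)), window=7)


class TestPSNR:
    def test_closed_form(self):
        x = np.zeros((10, 10))
        y = np.full((10, 10), 0.1)  # MSE = 0.01
        assert dis.psnr(x, y) == pytest.approx(20.0)

    def test_identical_images_infinite(self):
        x = np.random.default_rng(0).random((8, 8))
        assert np.isinf(dis.psnr(x, x))

    def test_matches_mse_formula(self):
        rng = np.random.default_rng(1)
        x, y = rng.random((12, 12)), rng.random((12, 12))
        mse = np.mean((x - y) ** 2)
        assert dis.psnr(x, y) == pytest.approx(10 * np.log10(1.0 / mse), rel=1e-12)


class TestFactorPCA:
    def test_orthogonal_inputs_recovered(self):
        """Sample-orthogonal factors with distinct variances come back as the
        components, up to sign and order."""
        rng = np.random.default_rng(0)
        raw = rng.normal(size=(200, 4))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        fac = pd.DataFrame(q * np.array([4.0, 3.0, 2.0, 1.0]), columns=list("abcd"))
        scores, _ = dis.factor_pca(fac, variance_target=0.999, standardize=False)
        corr = np.corrcoef(fac.to_numpy().T, scores.to_numpy().T)[:4, 4:]
        # |correlation| is a permutation matrix
        assert np.allclose(np.sort(np.abs(corr).max(axis=1)), 1.0, atol=1e-8)
        assert np.allclose(np.abs(corr).sum(), 4.0, atol=1e-6)

    def test_correlated_factors_reduce_components(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(300, 4))
        fac = pd.DataFrame(base, columns=list("abcd"))
        fac["e"] = fac["a"]  # perfect correlation
        scores, _ = dis.factor_pca(fac, variance_target=0.95)
        assert scores.shape[1] <= 4

    def test_scores_uncorrelated(self):
        rng = np.random.default_rng(2)
        fac = pd.DataFrame(rng.normal(size=(150, 5)), columns=list("abcde"))
        scores, _ = dis.factor_pca(fac, variance_target=0.999)
        c = np.corrcoef(scores.to_numpy().T)
        off = c - np.diag(np.diag(c))
        assert np.abs(off).max() < 1e-8

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        fac = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        fac["d"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            scores, loadings = dis.factor_pca(fac)
        assert "d" not in loadings.index


class TestImportanceMatrix:
    def _data(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        factors = pd.DataFrame(rng.normal(size=(n, 2)), columns=["f0", "f1"])
        latents = pd.DataFrame(
            {
                "a_z0": factors["f0"],  # exact copy of f0
                "a_z1": rng.normal(size=n),
                "a_z2": rng.normal(size=n),
            }
        )
        return latents, factors

    def test_copy_latent_dominates_column(self):
        latents, factors = self._data()
        imp = dis.importance_matrix(latents, factors, seed=1)
        col = imp.R[:, 0]
        assert col[0] / col.sum() >= 0.9

    def test_null_latents_uninformative(self):
        rng = np.random.default_rng(5)
        latents = pd.DataFrame(rng.normal(size=(400, 4)), columns=list("wxyz"))
        factors = pd.DataFrame(rng.normal(size=(400, 2)), columns=["f0", "f1"])
        imp = dis.importance_matrix(latents, factors, seed=1)
        assert imp.prediction_error.min() > 0.9  # normalized error ~ 1

    def test_duplicated_latent_splits_importance(self):
        latents, factors = self._data()
        dup = latents.copy()
        dup["a_z3"] = latents["a_z0"]
        a = dis.importance_matrix(latents, factors, seed=1)
        b = dis.importance_matrix(dup, factors, seed=1)
        assert b.R[:, 0].sum() == pytest.approx(a.R[:, 0].sum(), rel=0.10)
        assert b.R[3, 0] > 0  # the duplicate picks up part of the signal

    def test_too_few_samples_rejected(self):
        latents, factors = self._data(n=30)
        with pytest.raises(ValueError):
            dis.importance_matrix(latents, factors)

    def test_lasso_estimator(self):
        latents, factors = self._data()
        imp = dis.importance_matrix(latents, factors, estimator="lasso", seed=1)
        assert imp.R[0, 0] / (imp.R[:, 0].sum() + 1e-12) > 0.9


class TestDCIScores:
    def test_identity_importance_perfect(self):
        for k in (2, 5):
            s = dis.dci_scores(np.eye(k))
            assert s.disentanglement == pytest.approx(1.0)
            assert s.completeness == pytest.approx(1.0)

    def test_uniform_importance_zero(self):
        s = dis.dci_scores(np.full((4, 4), 0.25))
        assert s.disentanglement == pytest.approx(0.0, abs=1e-12)
        assert s.completeness == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_entropy(self):
        s = dis.dci_scores(np.array([[0.8, 0.2], [0.2, 0.8]]))
        h = -(0.8 * np.log(0.8) + 0.2 * np.log(0.2))
        expected = 1.0 - h / np.log(2)
        assert s.disentanglement == pytest.approx(expected, abs=1e-12)
        assert s.completeness == pytest.approx(expected, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            dis.dci_scores(np.zeros((3, 3)))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        R = rng.random((6, 4))
        s0 = dis.dci_scores(R)
        s1 = dis.dci_scores(R[rng.permutation(6)][:, rng.permutation(4)])
        assert s1.disentanglement == pytest.approx(s0.disentanglement, abs=1e-12)
        assert s1.completeness == pytest.approx(s0.completeness, abs=1e-12)


class TestMIG:
    def test_copy_latent_saturates(self):
        rng = np.random.default_rng(0)
        v = rng.integers(0, 10, size=5000).astype(float)
        latents = pd.DataFrame({"z0": v, "z1": rng.normal(size=5000)})
        factors = pd.DataFrame({"f": v})
        assert dis.mig(latents, factors, bins=10) == pytest.approx(1.0, abs=0.05)

    def test_independent_latents_near_zero(self):
        rng = np.random.default_rng(1)
        latents = pd.DataFrame(rng.normal(size=(5000, 3)), columns=list("abc"))
        factors = pd.DataFrame(rng.normal(size=(5000, 2)), columns=["f0", "f1"])
        assert dis.mig(latents, factors) == pytest.approx(0.0, abs=0.05)

    def test_plug_in_mi_matches_exhaustive_summation(self):
        """MI from a tabulated 4x4 joint equals the brute-force double sum."""
        joint = np.array(
            [[30, 5, 2, 1], [4, 25, 6, 2], [1, 7, 28, 3], [2, 1, 5, 40]], dtype=float
        )
        a = np.repeat(np.arange(4), joint.sum(axis=1).astype(int))
        b = np.concatenate([np.repeat(np.arange(4), joint[i].astype(int)) for i in range(4)])
        p = joint / joint.sum()
        brute = 0.0
        for i in range(4):
            for j in range(4):
                if p[i, j] > 0:
                    brute += p[i, j] * np.log(p[i, j] / (p[i].sum() * p[:, j].sum()))
        assert dis._mi_from_codes(a, b) == pytest.approx(brute, abs=1e-9)

    def test_monotone_transformation_invariance(self):
        rng = np.random.default_rng(2)
        latents = pd.DataFrame(rng.normal(size=(2000, 3)), columns=list("abc"))
        factors = pd.DataFrame({"f": latents["a"] + 0.3 * rng.normal(size=2000)})
        assert dis.mig(np.exp(latents), factors) == pytest.approx(
            dis.mig(latents, factors), abs=1e-12
        )

    def test_degenerate_factor_excluded(self):
        rng = np.random.default_rng(3)
        latents = pd.DataFrame(rng.normal(size=(500, 2)), columns=["a", "b"])
        factors = pd.DataFrame({"ok": rng.normal(size=500), "flat": np.ones(500)})
        with pytest.warns(UserWarning, match="degenerate"):
            val = dis.mig(latents, factors, bins=10)
        assert 0.0 <= val <= 1.0


class TestResampleEvaluate:
    def _population(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        factors = pd.DataFrame(rng.normal(size=(n, 2)), columns=["f0", "f1"])
        latents = pd.DataFrame(
            {
                "z0": factors["f0"] + 0.1 * rng.normal(size=n),
                "z1": factors["f1"] + 0.1 * rng.normal(size=n),
                "z2": rng.normal(size=n),
            }
        )
        return latents, factors

    def test_single_iteration_zero_sd(self):
        latents, factors = self._population()
        rep = dis.resample_evaluate(latents, factors, iters=1, n=200, seed=1)
        assert all(sd == 0.0 for _, sd in rep.metrics.values())

    def test_full_population_subsample_deterministic(self):
        latents, factors = self._population()
        rep = dis.resample_evaluate(latents, factors, iters=3, n=300, seed=2)
        # n == population: every iteration sees the same multiset
        assert rep.sd("D") == pytest.approx(0.0, abs=1e-12)

    def test_seeded_reproducibility(self):
        latents, factors = self._population()
        a = dis.resample_evaluate(latents, factors, iters=3, n=150, seed=3)
        b = dis.resample_evaluate(latents, factors, iters=3, n=150, seed=3)
        assert a.to_dict() == b.to_dict()

    def test_small_population_flags_replacement(self):
        latents, factors = self._population(n=100)
        rep = dis.resample_evaluate(latents, factors, iters=2, n=150, seed=4)
        assert rep.with_replacement

    def test_lpips_marked_not_computed(self):
        latents, factors = self._population()
        rep = dis.resample_evaluate(latents, factors, iters=1, n=100, seed=5)
        assert rep.lpips == "not computed"


class TestInterocularConsistency:
    def _report(self, d):
        return dis.EvalReport(metrics={"D": (d, 0.0), "C": (0.5, 0.0)}, iterations=1, n=10)

    def test_identical_reports_zero_delta(self):
        table = dis.interocular_consistency(self._report(0.4), self._report(0.4))
        assert (table["abs_diff"] == 0).all()
        assert table["within_tolerance"].all()

    def test_metric_mismatch_rejected(self):
        left = self._report(0.4)
        right = dis.EvalReport(metrics={"D": (0.4, 0.0)}, iterations=1, n=10)
        with pytest.raises(ValueError):
            dis.interocular_consistency(left, right)

    def test_tolerance_flag(self):
        table = dis.interocular_consistency(self._report(0.4), self._report(0.6), tolerance=0.1)
        assert not table.loc["D", "within_tolerance"]


def test_group_disentanglement_blocks():
    """A block-diagonal importance matrix yields perfect per-group scores and
    a mixed row drags only its own group down."""
    R = np.zeros((4, 4))
    R[0, 0] = R[1, 1] = 1.0  # group a: one factor each
    R[2, 2] = R[3, 3] = 1.0  # group b
    imp = dis.ImportanceMatrix(
        R=R, latent_names=["a_z0", "a_z1", "b_z0", "b_z1"],
        factor_names=list("wxyz"), estimator="manual",
        prediction_error=np.zeros(4),
    )
    out = dis.group_disentanglement(imp)
    assert out["a"] == pytest.approx(1.0)
    assert out["b"] == pytest.approx(1.0)
    R2 = R.copy()
    R2[3] = 0.25  # one group-b latent spreads over every factor
    imp2 = dis.ImportanceMatrix(
        R=R2, latent_names=imp.latent_names, factor_names=imp.factor_names,
        estimator="manual", prediction_error=np.zeros(4),
    )
    out2 = dis.group_disentanglement(imp2)
    assert out2["a"] == pytest.approx(1.0)
    assert out2["b"] < 1.0
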