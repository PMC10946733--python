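"""GLM tests: design construction, OLS/contrast oracles, second-level F
statistics and cluster-extent inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from touchersp.config import CELLS, CONDITIONS, TEXTURES
from touchersp.glm import (
    CONTRASTS,
    GlmError,
    build_design,
    cluster_threshold,
    extract_cluster_power,
    fit_first_level,
    second_level_F,
)


def trial_table(n_per_cell=3, rng=None, cv=None):
    rows = []
    i = 0
    for tex in TEXTURES:
        for cond in CONDITIONS:
            for _ in range(n_per_cell):
                rows.append(
                    {
                        "trial": i,
                        "texture": tex,
                        "condition": cond,
                        "median_friction": 0.4 + (0.1 if tex == "hessian" else 0.0),
                        "median_load": 100.0,
                    }
                )
                i += 1
    df = pd.DataFrame(rows)
    if rng is not None:
        df["median_friction"] += rng.normal(0, 0.05, len(df))
        df["median_load"] += rng.normal(0, 10.0, len(df))
    if cv is not None:
        df["median_friction"] = cv
        df["median_load"] = 0.0
    return df


class TestBuildDesign:
    def test_one_per_cell_identity(self):
        X = build_design(trial_table(1), covariates=()).X
        block = X[list(CELLS)].to_numpy()
        assert block.shape == (6, 6)
        assert (block.sum(axis=1) == 1).all()
        # up to row order the dummy block is the 6x6 identity
        assert np.array_equal(np.sort(np.argmax(block, axis=1)), np.arange(6))

    def test_covariates_centred_and_rank(self, rng):
        d = build_design(trial_table(4, rng=rng))
        cv_cols = [c for c in d.X.columns if c.startswith("CV_")]
        assert len(cv_cols) == 6
        assert np.max(np.abs(d.X[cv_cols].mean())) < 1e-12
        assert np.linalg.matrix_rank(d.values) == 12

    def test_cell_centring_mode(self, rng):
        d = build_design(trial_table(4, rng=rng), centring="cell")
        for cell in CELLS:
            col = d.X[f"CV_{cell}"]
            nz = col[d.X[cell] == 1.0]
            assert abs(nz.mean()) < 1e-12

    def test_empty_cell_rejected(self):
        t = trial_table(2)
        t = t[~((t.texture == "silk") & (t.condition == "hedonic"))]
        with pytest.raises(GlmError, match="HS"):
            build_design(t, covariates=())

    def test_standardised_sum_reduces_collinearity(self, rng):
        """z-scoring behaviours before summation removes the covariate's
        cell-mean offset, decorrelating each modulator column from its cell
        dummy (the raw N + g sum has mean/SD ~ 5, making the pair nearly
        collinear and inflating first-level contrast variance)."""
        t = trial_table(6, rng=rng)
        t["median_load"] += 80.0  # grams-scale offset, as in real data
        raw = build_design(t)
        std = build_design(t, standardise=True)

        def max_dummy_corr(d):
            return max(
                abs(np.corrcoef(d.X[cell], d.X[f"CV_{cell}"])[0, 1])
                for cell in ("HH", "SH")
                if f"CV_{cell}" in d.X
            )

        assert max_dummy_corr(raw) > 0.9
        assert max_dummy_corr(std) < max_dummy_corr(raw) - 0.2
        # variance: contrast noise on pure-noise data shrinks markedly
        y = rng.standard_normal((len(t), 200))
        sd_raw = np.std(fit_first_level(y, raw, ["texture"])["texture"])
        sd_std = np.std(fit_first_level(y, std, ["texture"])["texture"])
        assert sd_std < 0.75 * sd_raw

    def test_missing_covariate_rejected(self):
        t = trial_table(2).drop(columns=["median_load"])
        with pytest.raises(GlmError):
            build_design(t)


class TestFirstLevel:
    def test_noiseless_recovery(self, rng):
        d = build_design(trial_table(4, rng=rng))
        X = d.values
        beta_true = rng.standard_normal((12, 7))
        Y = X @ beta_true
        imgs = fit_first_level(Y, d)
        for name, c6 in CONTRASTS.items():
            c = d.contrast_vector(name)
            np.testing.assert_allclose(imgs[name], c @ beta_true, atol=1e-10)

    def test_beta_matches_normal_equations(self, rng):
        d = build_design(trial_table(3, rng=rng))
        X = d.values
        y = rng.standard_normal((X.shape[0], 1))
        got = fit_first_level(y, d, contrasts=["texture"])["texture"]
        beta = np.linalg.solve(X.T @ X, X.T @ y[:, 0])
        expect = d.contrast_vector("texture") @ beta
        assert got[0] == pytest.approx(expect, abs=1e-10)

    def test_centring_invariance(self, rng):
        """Adding a constant to the covariate before centring leaves contrast
        images unchanged under per-cell centring, and leaves the fitted
        values (model span) unchanged under whole-column centring."""
        t = trial_table(4, rng=rng)
        t2 = t.copy()
        t2["median_load"] += 500.0
        y = rng.standard_normal((len(t), 5))

        d1 = build_design(t, centring="cell")
        d2 = build_design(t2, centring="cell")
        img1 = fit_first_level(y, d1)
        img2 = fit_first_level(y, d2)
        for name in CONTRASTS:
            np.testing.assert_allclose(img1[name], img2[name], atol=1e-8)

        for da, db in ((build_design(t), build_design(t2)),):
            Xa, Xb = da.values, db.values
            ha = Xa @ np.linalg.pinv(Xa) @ y
            hb = Xb @ np.linalg.pinv(Xb) @ y
            np.testing.assert_allclose(ha, hb, atol=1e-8)

    def test_rank_deficient_named(self):
        t = trial_table(2, cv=np.ones(12))  # constant covariate -> dropped, fine
        d = build_design(t)
        assert not any(c.startswith("CV_") for c in d.X.columns)
        # duplicate a dummy column to force deficiency
        d.X["HH2"] = d.X["HH"]
        with pytest.raises(GlmError, match="rank-deficient"):
            fit_first_level(np.zeros((12, 2)), d)


class TestSecondLevel:
    def test_one_sample_limits(self, rng):
        vals = np.array([1.0, 1.0, 1.0, 1.0])[:, None] + rng.normal(0, 1e-6, (4, 1))
        F, df = second_level_F(vals, "one_sample")
        assert df == (1.0, 3.0)
        assert F[0] > 1e8
        alt = np.array([1.0, -1.0, 1.0, -1.0])[:, None]
        F2, _ = second_level_F(alt, "one_sample")
        assert F2[0] == pytest.approx(0.0, abs=1e-12)

    def test_one_sample_equals_t_squared(self, rng):
        Y = rng.standard_normal((8, 20))
        F, df = second_level_F(Y, "one_sample")
        t = sp_stats.ttest_1samp(Y, 0.0, axis=0).statistic
        np.testing.assert_allclose(F, t**2, atol=1e-10)

    def test_paired_two_contrast_equals_glm_oracle(self, rng):
        """The two-column F equals an explicitly constructed GLM F-test
        (residual sum-of-squares form)."""
        n = 7
        b1 = rng.standard_normal((n, 5))
        b2 = rng.standard_normal((n, 5))
        F, df = second_level_F([b1, b2], "paired_two_contrast")
        assert df == (2.0, 2 * n - 2)
        # oracle: X = [1_n 0; 0 1_n], F = ((RSS0-RSS1)/2) / (RSS1/(N-2))
        X = np.zeros((2 * n, 2))
        X[:n, 0] = 1.0
        X[n:, 1] = 1.0
        Y = np.vstack([b1, b2])
        beta = np.linalg.lstsq(X, Y, rcond=None)[0]
        rss1 = ((Y - X @ beta) ** 2).sum(axis=0)
        rss0 = (Y**2).sum(axis=0)
        oracle = ((rss0 - rss1) / 2) / (rss1 / (2 * n - 2))
        np.testing.assert_allclose(F, oracle, atol=1e-10)

    def test_mismatched_blocks_rejected(self, rng):
        with pytest.raises(GlmError):
            second_level_F([rng.standard_normal((4, 3)), rng.standard_normal((5, 3))],
                           "paired_two_contrast")


class TestClusterThreshold:
    def _fmap(self, shape=(10, 10, 10)):
        return np.zeros(shape)

    def test_extent_boundary(self):
        df = (1.0, 30.0)
        thr = sp_stats.f.isf(0.001, *df)
        F = self._fmap()
        F[1:5, 1:5, 1:3] = thr + 1  # 4*4*2 = 32 voxels < 35
        assert cluster_threshold(F, df) == []
        F[1:5, 1:6, 1:3] = thr + 1  # 40 voxels
        out = cluster_threshold(F, df)
        assert len(out) == 1 and out[0].k == 40

    def test_corner_touch_separates_under_18(self):
        """Two blobs sharing only a corner (vertex) are separate components
        under 18-connectivity, one component under 26."""
        df = (1.0, 30.0)
        thr = sp_stats.f.isf(0.001, *df)
        F = np.zeros((6, 6, 6))
        F[0:2, 0:2, 0:2] = thr + 1
        F[2:4, 2:4, 2:4] = thr + 1
        out18 = cluster_threshold(F, df, k_min=1, connectivity=18)
        out26 = cluster_threshold(F, df, k_min=1, connectivity=26)
        assert len(out18) == 2
        assert len(out26) == 1

    def test_edge_touch_joins_under_18(self):
        df = (1.0, 30.0)
        thr = sp_stats.f.isf(0.001, *df)
        F = np.zeros((6, 6, 6))
        F[0:2, 0:2, 0:2] = thr + 1
        F[2:4, 2:4, 1] = thr + 1  # shares an edge at (2,2,1)-(1,1,1)? use explicit
        out6 = cluster_threshold(F, df, k_min=1, connectivity=6)
        out18 = cluster_threshold(F, df, k_min=1, connectivity=18)
        assert len(out18) <= len(out6)

    def test_threshold_quantile_oracle(self):
        """The voxel threshold equals the upper-tail F quantile, checked via
        the t-distribution identity F(1, v; p) = t(v; p/2)^2, and decreases
        with df2."""
        thr = cluster_threshold.__wrapped__ if hasattr(cluster_threshold, "__wrapped__") else None
        f_q = sp_stats.f.isf(0.001, 1, 30)
        t_q = sp_stats.t.isf(0.0005, 30)
        assert f_q == pytest.approx(t_q**2, rel=1e-10)
        qs = [sp_stats.f.isf(0.001, 1, v) for v in (5, 10, 30, 100)]
        assert all(a > b for a, b in zip(qs, qs[1:]))
        df = (1.0, 30.0)
        F = self._fmap()
        F[0:4, 0:4, 0:4] = f_q + 1e-9  # just above
        out = cluster_threshold(F, df, k_min=1)
        assert len(out) == 1
        F[0:4, 0:4, 0:4] = f_q - 1e-9  # just below: strict
        assert cluster_threshold(F, df, k_min=1) == []

    def test_nan_outside_mask_excluded(self):
        df = (1.0, 10.0)
        F = np.full((5, 5, 5), np.nan)
        F[1:4, 1:4, 1:4] = 1e6
        out = cluster_threshold(F, df, k_min=1)
        assert out[0].k == 27

    def test_peak_tie_break(self):
        df = (1.0, 10.0)
        thr = sp_stats.f.isf(0.001, *df)
        F = np.zeros((5, 5, 5))
        F[1:4, 1:4, 1:4] = thr + 1
        F[3, 3, 3] = thr + 5
        F[1, 1, 1] = thr + 5  # tie: earliest latency then lowest y, x
        out = cluster_threshold(F, df, k_min=1)
        assert (out[0].peak_ix, out[0].peak_iy, out[0].peak_it) == (1, 1, 1)

    def test_bad_p_rejected(self):
        with pytest.raises(GlmError):
            cluster_threshold(np.zeros((3, 3, 3)), (1, 10), p_form=1.5)


class TestExtractPower:
    def test_constant_and_single_voxel(self):
        df = (1.0, 10.0)
        F = np.zeros((5, 5, 5))
        F[1:4, 1:4, 1:4] = 1e3
        clusters = cluster_threshold(F, df, k_min=1)
        imgs = {("s1", "hessian"): np.full((5, 5, 5), 2.5),
                ("s1", "silk"): np.full((5, 5, 5), -1.5)}
        out = extract_cluster_power(clusters, imgs)
        assert set(out["condition"]) == {"hessian", "silk"}
        assert out[out.condition == "hessian"]["mean_db"].iloc[0] == pytest.approx(2.5)

    def test_matches_loop_oracle(self, rng):
        df = (1.0, 10.0)
        F = np.zeros((6, 6, 6))
        F[2:5, 1:4, 0:3] = 1e3
        clusters = cluster_threshold(F, df, k_min=1)
        img = rng.standard_normal((6, 6, 6))
        out = extract_cluster_power(clusters, {("s1", "hessian"): img})
        vox = clusters[0].voxels
        oracle = np.mean([img[tuple(v)] for v in vox])
        assert out["mean_db"].iloc[0] == pytest.approx(oracle, abs=1e-12)
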