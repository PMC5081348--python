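import numpy as np
import pytest

from saccdecode.atlas import GridSpec, build_atlas
from saccdecode.bold import EffectSpec, NoiseParams, simulate_subject
from saccdecode.design import DesignParams, make_experiment_design
from saccdecode.glm import (
    CONTRAST_ADAPTATION,
    CONTRAST_LARGE_MINUS_SMALL,
    DesignMatrix,
    GlmConfig,
    build_design_matrix,
    compute_contrast,
    fit_glm,
    fit_run,
    gaussian_highpass,
    smooth_volume,
)

TR = 2.0


class TestHighpass:
    def test_linear_drift_removed(self):
        t = np.arange(200) * TR
        y = 3.0 + 0.05 * t
        out = gaussian_highpass(y, 50.0, TR)
        assert np.ptp(out) <= 1e-6 * 0.05  # constant up to numerical error

    def test_constant_unchanged(self):
        y = np.full(150, 7.5)
        np.testing.assert_allclose(gaussian_highpass(y, 50.0, TR), y, atol=1e-10)

    def test_block_frequency_retained(self):
        # transfer at sinusoids bracketing the ~1/11 Hz block rate: >= 90% amplitude
        t = np.arange(220) * TR
        for freq in (1.0 / 14, 1.0 / 11, 1.0 / 8):
            y = np.sin(2 * np.pi * freq * t)
            out = gaussian_highpass(y, 50.0, TR)
            gain = np.ptp(out[20:-20]) / np.ptp(y[20:-20])
            assert gain >= 0.9

    def test_mean_restored(self):
        # the overall signal level survives filtering (mean added back)
        rng = np.random.default_rng(0)
        y = rng.normal(5.0, 1.0, size=180)
        out = gaussian_highpass(y, 50.0, TR)
        assert out.mean() == pytest.approx(y.mean(), abs=0.05)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            gaussian_highpass(np.ones(2), 50.0, TR)

    def test_2d_input(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(100, 5))
        out = gaussian_highpass(y, 50.0, TR)
        assert out.shape == y.shape


class TestDesignMatrix:
    def test_per_block_79_columns(self, one_run):
        dm = build_design_matrix(one_run, GlmConfig(mode="per_block"))
        assert dm.matrix.shape[1] == 36 + 36 + 6 + 1 == 79

    def test_per_condition_19_columns(self, one_run):
        dm = build_design_matrix(one_run, GlmConfig(mode="per_condition"))
        assert dm.matrix.shape[1] == 6 + 6 + 6 + 1 == 19
        assert dm.main_labels[0] == "large_left"

    def test_no_derivatives_option(self, one_run):
        dm = build_design_matrix(one_run, GlmConfig(include_temporal_derivatives=False))
        assert dm.matrix.shape[1] == 36 + 6 + 1

    def test_derivative_columns_sum_to_zero(self, one_run):
        # holds for blocks whose response completes within the run; the last
        # blocks' kernels are truncated by the run end
        dm = build_design_matrix(one_run, GlmConfig(mode="per_block"))
        complete = {
            f"block_{b.index:02d}_deriv"
            for b in one_run.blocks
            if b.onset_s + b.duration_s + 32.0 <= one_run.duration_s
        }
        assert complete
        for label, col in zip(dm.labels, dm.matrix.T):
            if label in complete:
                assert abs(col.sum()) < 0.05 * np.abs(col).sum()

    def test_overlapping_blocks_rejected(self, one_run, default_params):
        from dataclasses import replace

        bad_blocks = list(one_run.blocks)
        bad_blocks[1] = replace(bad_blocks[1], onset_s=bad_blocks[0].onset_s + 1.0)
        bad_run = replace(one_run, blocks=tuple(bad_blocks))
        with pytest.raises(ValueError, match="overlap"):
            build_design_matrix(bad_run, GlmConfig())


class TestFitGlm:
    def test_noiseless_recovery(self, one_run, tiny_atlas):
        design = make_experiment_design(DesignParams(), seed=3, n_runs=1)
        noiseless = NoiseParams(sd=0, baseline=50.0, baseline_run_sd=0, drift_sd=0)
        runs, truth = simulate_subject(
            design, tiny_atlas, EffectSpec.paper_like(), noiseless, seed=1
        )
        fit = fit_run(runs[0], design.runs[0], GlmConfig())
        betas = np.array(
            [fit.beta(f"block_{b.index:02d}") for b in design.runs[0].blocks]
        )
        np.testing.assert_allclose(betas, truth.amplitudes[0], atol=1e-6)

    def test_pure_noise_betas_near_zero(self, one_run):
        rng = np.random.default_rng(0)
        dm = build_design_matrix(one_run, GlmConfig())
        n_vox = 400
        data = rng.normal(0, 1.0, size=(one_run.n_volumes, n_vox))
        fit = fit_glm(data, dm)
        block_rows = [i for i, l in enumerate(fit.labels) if l.startswith("block_")
                      and not l.endswith("_deriv")]
        means = fit.betas[block_rows].mean(axis=1)
        se = fit.betas[block_rows].std(axis=1, ddof=1) / np.sqrt(n_vox)
        assert np.all(np.abs(means) < 3.5 * se + 1e-3)

    def test_duplicated_column_raises(self, one_run):
        dm = build_design_matrix(one_run, GlmConfig())
        X = dm.matrix.copy()
        X[:, 1] = X[:, 0]
        with pytest.raises(ValueError, match="collinear"):
            fit_glm(np.zeros((X.shape[0], 2)), DesignMatrix(X, dm.labels, dm.main_labels))

    def test_zero_motion_columns_are_inert(self, one_run):
        dm = build_design_matrix(one_run, GlmConfig())
        fit = fit_glm(np.ones((one_run.n_volumes, 3)), dm)
        for j, label in enumerate(fit.labels):
            if label.startswith("motion_"):
                assert np.all(fit.betas[j] == 0)

    def test_rmse_scales_with_noise_sd(self, tiny_atlas):
        """log-log slope of beta RMSE vs noise SD is 1 (linear estimator)."""
        design = make_experiment_design(DesignParams(), seed=5, n_runs=1)
        sds = [0.5, 1.0, 2.0]
        rmses = []
        for sd in sds:
            errs = []
            for seed in range(5):
                noise = NoiseParams(sd=sd, baseline=0, baseline_run_sd=0, drift_sd=0)
                runs, truth = simulate_subject(
                    design, tiny_atlas, EffectSpec.null(), noise, seed=seed
                )
                fit = fit_run(runs[0], design.runs[0], GlmConfig())
                betas = np.array(
                    [fit.beta(f"block_{b.index:02d}") for b in design.runs[0].blocks]
                )
                errs.append(np.sqrt(np.mean((betas - truth.amplitudes[0]) ** 2)))
            rmses.append(np.mean(errs))
        slope = np.polyfit(np.log(sds), np.log(rmses), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)


class TestContrast:
    def test_zero_weights(self):
        betas = {c: np.ones(5) for c in CONTRAST_LARGE_MINUS_SMALL}
        out = compute_contrast(betas, {c: 0.0 for c in betas})
        np.testing.assert_array_equal(out, np.zeros(5))

    def test_equal_betas_give_zero_map(self):
        betas = {c: np.full(5, 3.3) for c in CONTRAST_LARGE_MINUS_SMALL}
        out = compute_contrast(betas, CONTRAST_LARGE_MINUS_SMALL)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_adaptation_weights_sum_to_zero(self):
        assert sum(CONTRAST_ADAPTATION.values()) == pytest.approx(0.0)
        assert sum(CONTRAST_LARGE_MINUS_SMALL.values()) == pytest.approx(0.0)

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError, match="without betas"):
            compute_contrast({"large_left": np.ones(2)}, CONTRAST_LARGE_MINUS_SMALL)

    def test_filter_vs_drift_regressors_agree(self, tiny_atlas):
        """Highpass-then-fit and drift-regressors-in-model give similar contrasts."""
        design = make_experiment_design(DesignParams(), seed=7, n_runs=1)
        run = design.runs[0]
        noise = NoiseParams(sd=0.5, baseline=10.0, baseline_run_sd=0, drift_sd=2.0)
        runs, _ = simulate_subject(design, tiny_atlas, EffectSpec.paper_like(), noise, seed=3)
        cfg = GlmConfig(mode="per_condition")

        fit_a = fit_run(runs[0], run, cfg)
        betas_a = {c: fit_a.beta(c) for c in CONTRAST_LARGE_MINUS_SMALL}
        con_a = compute_contrast(betas_a, CONTRAST_LARGE_MINUS_SMALL)

        dm = build_design_matrix(run, cfg, n_volumes=runs[0].n_volumes)
        n = runs[0].n_volumes
        drift = np.linspace(-0.5, 0.5, n)[:, None]
        X = np.column_stack([dm.matrix, drift])
        dm_b = DesignMatrix(X, dm.labels + ["drift"], dm.main_labels)
        fit_b = fit_glm(runs[0].data.T, dm_b)
        betas_b = {c: fit_b.beta(c) for c in CONTRAST_LARGE_MINUS_SMALL}
        con_b = compute_contrast(betas_b, CONTRAST_LARGE_MINUS_SMALL)

        denom = np.abs(con_a).mean()
        assert np.abs(con_a - con_b).mean() <= 0.05 * max(denom, 1e-12) + 0.02


class TestSmoothVolume:
    GRID = GridSpec(voxel_size_mm=(2, 2, 2), origin_mm=(0, 0, 0), shape=(21, 21, 21))

    def test_fwhm_zero_identity(self, rng):
        vol = rng.normal(size=self.GRID.shape)
        np.testing.assert_array_equal(smooth_volume(vol, 0.0, self.GRID), vol)

    def test_delta_mass_preserved(self):
        vol = np.zeros(self.GRID.shape)
        vol[10, 10, 10] = 1.0
        out = smooth_volume(vol, 5.0, self.GRID)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)

    def test_constant_unchanged(self):
        vol = np.full(self.GRID.shape, 4.2)
        np.testing.assert_allclose(smooth_volume(vol, 5.0, self.GRID), vol, atol=1e-10)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_volume(np.zeros(self.GRID.shape), -1.0, self.GRID)
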