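"""First-component PLS pathway model: LOSO validation, bootstrap, confounds."""

import numpy as np
import pytest

import escapekit as ek
from escapekit.errors import ParameterError
from escapekit.pathway import PathwayBlocks, SubjectBlock


class TestFirstComponent:
    def test_matches_reference_pls_implementation(self):
        from sklearn.cross_decomposition import PLSSVD
        blocks, _ = ek.generate_fmri_blocks(6, 30, (25, 10), noise_sd=0.5,
                                            seed=0)
        X = blocks.stacked(region="predictor")
        Y = blocks.stacked(region="outcome")
        wx, wy, _, _ = ek.pls_first_component(X, Y)
        ref = PLSSVD(n_components=1, scale=False).fit(X, Y)
        rx, ry = ref.x_weights_[:, 0], ref.y_weights_[:, 0]
        if rx[np.argmax(np.abs(rx))] < 0:
            rx, ry = -rx, -ry
        assert np.allclose(wx, rx, atol=1e-8)
        assert np.allclose(wy, ry, atol=1e-8)

    def test_sign_convention(self):
        blocks, _ = ek.generate_fmri_blocks(4, 30, (25, 10), seed=1)
        wx, *_ = ek.pls_first_component(blocks.stacked(region="predictor"),
                                        blocks.stacked(region="outcome"))
        assert wx[np.argmax(np.abs(wx))] > 0


class TestLosoPathway:
    def test_noiseless_shared_latent_perfect_correlation(self):
        blocks, _ = ek.generate_fmri_blocks(8, 30, (40, 15), noise_sd=0.0,
                                            seed=2)
        m = ek.fit_pls_pathway(blocks)
        assert np.all(m.loso_correlations > 0.999)

    def test_independent_blocks_centered_at_zero(self):
        means = []
        for seed in range(5):
            blocks, _ = ek.generate_fmri_blocks(8, 30, (40, 15),
                                                shared_gain=0.0, seed=seed)
            means.append(np.nanmean(
                ek.fit_pls_pathway(blocks).loso_correlations))
        assert abs(np.mean(means)) < 0.1

    def test_correlation_grows_with_latent_strength(self):
        prev = -1.0
        for gain in (0.3, 1.0, 3.0):
            vals = []
            for seed in range(3):
                blocks, _ = ek.generate_fmri_blocks(
                    8, 30, (40, 15), shared_gain=gain, noise_sd=1.0,
                    seed=seed)
                vals.append(np.nanmean(
                    ek.fit_pls_pathway(blocks).loso_correlations))
            assert np.mean(vals) > prev
            prev = np.mean(vals)

    def test_scale_invariance(self):
        blocks, _ = ek.generate_fmri_blocks(6, 30, (25, 10), noise_sd=0.5,
                                            seed=3)
        scaled = PathwayBlocks(subjects=[
            SubjectBlock(predictor=7.0 * s.predictor,
                         outcome=0.3 * s.outcome,
                         covariates=s.covariates)
            for s in blocks.subjects])
        a = ek.fit_pls_pathway(blocks).loso_correlations
        b = ek.fit_pls_pathway(scaled).loso_correlations
        assert np.allclose(a, b, atol=1e-10)

    def test_training_never_sees_held_out_subject(self):
        """Perturbing one subject's data leaves the weights fitted without
        that subject unchanged."""
        blocks, _ = ek.generate_fmri_blocks(5, 20, (15, 8), noise_sd=0.5,
                                            seed=4)
        Xtr = blocks.stacked(exclude=0, region="predictor")
        Ytr = blocks.stacked(exclude=0, region="outcome")
        wx, *_ = ek.pls_first_component(Xtr, Ytr)
        blocks.subjects[0].predictor *= 100.0
        Xtr2 = blocks.stacked(exclude=0, region="predictor")
        wx2, *_ = ek.pls_first_component(Xtr2,
                                         blocks.stacked(exclude=0,
                                                        region="outcome"))
        assert np.array_equal(wx, wx2)

    def test_too_few_subjects(self):
        blocks, _ = ek.generate_fmri_blocks(2, 20, (10, 5), seed=5)
        with pytest.raises(ParameterError):
            ek.fit_pls_pathway(blocks)


class TestBootstrapLocalization:
    def test_single_bootstrap_rejected(self):
        blocks, _ = ek.generate_fmri_blocks(4, 20, (10, 5), seed=6)
        with pytest.raises(ParameterError):
            ek.bootstrap_voxel_contributions(blocks, n_boot=1)

    def test_planted_loading_voxels_recovered(self):
        load = np.zeros(50)
        load[:5] = 1.0
        blocks, _ = ek.generate_fmri_blocks(
            12, 40, (50, 20), predictor_loadings=load, shared_gain=2.0,
            noise_sd=1.0, seed=7)
        maps = ek.bootstrap_voxel_contributions(blocks, n_boot=400, seed=8)
        sig = maps["predictor"]["q"] < 0.05
        assert sig[:5].all()
        assert sig[5:].sum() <= 2

    def test_pure_noise_blocks_rarely_flag_voxels(self):
        fdps = []
        for seed in range(3):
            blocks, _ = ek.generate_fmri_blocks(10, 30, (30, 12),
                                                shared_gain=0.0,
                                                noise_sd=1.0, seed=seed)
            maps = ek.bootstrap_voxel_contributions(blocks, n_boot=300,
                                                    seed=seed)
            n_sig = int((maps["predictor"]["q"] < 0.05).sum())
            fdps.append(n_sig / 30)
        assert np.mean(fdps) <= 0.05


class TestPartialCorrelation:
    def test_confound_driven_pathway_collapses(self):
        parts, raws = [], []
        for seed in range(3):
            blocks, _ = ek.generate_fmri_blocks(
                10, 40, (30, 15), n_confound_voxels=20, shared_gain=0.0,
                confound_gain=1.0, noise_sd=0.5, seed=seed)
            raw, part = ek.partial_pathway_correlation(blocks)
            raws.append(raw)
            parts.append(part)
        assert np.mean(raws) > 0.6
        assert abs(np.mean(parts)) < 0.2

    def test_genuine_pathway_survives_control(self):
        blocks, _ = ek.generate_fmri_blocks(
            10, 40, (30, 15), n_confound_voxels=20, shared_gain=2.0,
            confound_gain=1.0, noise_sd=0.5, seed=20)
        raw, part = ek.partial_pathway_correlation(blocks)
        assert part > 0.5

    def test_irrelevant_confound_leaves_correlation(self):
        blocks, _ = ek.generate_fmri_blocks(
            10, 40, (30, 15), n_confound_voxels=20, shared_gain=2.0,
            confound_gain=0.0, noise_sd=0.5, seed=21)
        raw, part = ek.partial_pathway_correlation(blocks)
        assert part == pytest.approx(raw, abs=0.05)

    def test_missing_confound_block_rejected(self):
        blocks, _ = ek.generate_fmri_blocks(5, 20, (10, 5), seed=22)
        with pytest.raises(ParameterError):
            ek.partial_pathway_correlation(blocks)


class TestConditionContrast:
    def test_equal_gain_contrast_centered_at_zero(self):
        stats = []
        for seed in range(5):
            blocks, _ = ek.generate_fmri_blocks(10, 48, (30, 15),
                                                shared_gain=1.0,
                                                noise_sd=0.5, seed=seed)
            m = ek.fit_pls_pathway(blocks)
            res = ek.pathway_condition_contrast(m,
                                                blocks.stacked_covariates())
            stats.append(res["contrast_stat"])
        assert abs(np.mean(stats)) < 0.15

    def test_planted_intensity_slope_gives_positive_trend(self):
        hits = 0
        for seed in range(10):
            blocks, _ = ek.generate_fmri_blocks(
                10, 48, (30, 15), shared_gain=1.0, noise_sd=0.5,
                condition_effect=1.0, intensity_slope=0.5, seed=seed)
            m = ek.fit_pls_pathway(blocks)
            res = ek.pathway_condition_contrast(m,
                                                blocks.stacked_covariates())
            hits += res["trend_stat"] > 0 and res["contrast_stat"] > 0
        assert hits >= 9

    def test_single_subject_flags_inference_unavailable(self):
        blocks, _ = ek.generate_fmri_blocks(3, 48, (20, 10), shared_gain=1.0,
                                            seed=30)
        m = ek.fit_pls_pathway(blocks)
        one = blocks.subjects[:1]
        import pandas as pd
        cov = one[0].covariates.copy()
        from escapekit.pathway import PathwayModel
        k = one[0].n_trials
        m1 = PathwayModel(x_weights=m.x_weights, y_weights=m.y_weights,
                          loso_correlations=np.array([np.nan]),
                          x_scores=m.x_scores[:k], y_scores=m.y_scores[:k],
                          subject_index=np.zeros(k, dtype=int))
        res = ek.pathway_condition_contrast(m1, cov)
        assert not res["inference_available"]
        assert np.isnan(res["contrast_p"])
        assert np.isfinite(res["contrast_stat"])
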