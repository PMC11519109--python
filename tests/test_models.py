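"""Reconstruction/detection model contracts and the surrogate detector."""

import dataclasses

import numpy as np
import pytest

from diagqm import (
    DetectTrainConfig,
    ImageVolume,
    MaskConfig,
    ReconModel,
    ReconTrainConfig,
    SurrogateParams,
    detect_chain,
    make_undersampling_mask,
    predict_heatmap,
    recon_chain,
    reconstruct,
    ssim,
    surrogate_detect,
    train_detector,
    train_reconstructor,
    undersample_volume,
)


def _paired_cohort(config, cases, acceleration=4.0):
    refs, aliased = [], []
    for i, case in enumerate(cases):
        ref = recon_chain(
            case.image, crop_size=config.volume_shape,
            in_plane_spacing=config.voxel_spacing[0],
        )
        mask = make_undersampling_mask(
            case.image.shape[0], MaskConfig(acceleration, seed=500 + i)
        )
        nv = recon_chain(
            undersample_volume(case.image, mask),
            crop_size=config.volume_shape,
            in_plane_spacing=config.voxel_spacing[0],
        )
        refs.append(ref)
        aliased.append(nv)
    return aliased, refs


class TestReconstructor:
    def test_untrained_model_is_identity_and_clips(self, rng):
        model = ReconModel(model_scale=4, seed=0)
        vol = ImageVolume(rng.random((16, 16, 2)))
        out = reconstruct(model, vol)
        assert out.shape == vol.shape
        assert np.allclose(out.data, np.clip(vol.data, 0, 1))

    def test_zero_epochs_returns_initialisation(self, desk_phantom_config, small_cohort):
        aliased, refs = _paired_cohort(desk_phantom_config, small_cohort[:4])
        cfg = ReconTrainConfig(model_scale=4, epochs=0, seed=1)
        model = train_reconstructor(list(zip(aliased, refs)), cfg)
        fresh = ReconModel(model_scale=4, seed=1)
        for a, b in zip(model.net.params, fresh.net.params):
            assert np.array_equal(a, b)

    def test_training_is_deterministic(self, desk_phantom_config, small_cohort):
        aliased, refs = _paired_cohort(desk_phantom_config, small_cohort[:5])
        cfg = ReconTrainConfig(model_scale=4, epochs=2, learning_rate=2e-3, seed=7)
        m1 = train_reconstructor(list(zip(aliased, refs)), cfg)
        m2 = train_reconstructor(list(zip(aliased, refs)), cfg)
        assert m1.val_losses == m2.val_losses
        for a, b in zip(m1.net.params, m2.net.params):
            assert np.array_equal(a, b)

    def test_training_improves_held_out_ssim_over_naive(
        self, desk_phantom_config, small_cohort
    ):
        """The learned map should beat zero-filled IFFT on unseen phantoms."""
        aliased, refs = _paired_cohort(desk_phantom_config, small_cohort)
        cfg = ReconTrainConfig(model_scale=6, epochs=6, learning_rate=2e-3, seed=0)
        model = train_reconstructor(list(zip(aliased[:8], refs[:8])), cfg)
        naive = np.mean([ssim(refs[i], aliased[i]) for i in range(8, 12)])
        learned = np.mean(
            [ssim(refs[i], reconstruct(model, aliased[i])) for i in range(8, 12)]
        )
        assert learned > naive

    def test_output_range_is_clipped(self, desk_phantom_config, small_cohort):
        aliased, refs = _paired_cohort(desk_phantom_config, small_cohort[:4])
        cfg = ReconTrainConfig(model_scale=4, epochs=1, learning_rate=2e-3, seed=2)
        model = train_reconstructor(list(zip(aliased, refs)), cfg)
        out = reconstruct(model, aliased[0])
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0

    def test_too_few_pairs_rejected(self, desk_phantom_config, small_cohort):
        aliased, refs = _paired_cohort(desk_phantom_config, small_cohort[:1])
        with pytest.raises(ValueError):
            train_reconstructor([(aliased[0], refs[0])], ReconTrainConfig())


def _detect_cohort(config, cases):
    return [
        (
            detect_chain(
                c.image, crop_size=config.volume_shape,
                target_spacing=config.voxel_spacing,
            ),
            c.lesions,
        )
        for c in cases
    ]


@pytest.fixture(scope="module")
def trained(desk_phantom_config):
    import diagqm

    cfg = dataclasses.replace(desk_phantom_config, lesion_prevalence=0.6, seed=21)
    cases = diagqm.generate_cohort(cfg, 25)
    cohort = _detect_cohort(cfg, cases[:18])
    train_cfg = DetectTrainConfig(
        model_scale=4, epochs=3, n_folds=3, learning_rate=3e-3, seed=0
    )
    ensemble = train_detector(
        cohort, train_cfg, patient_ids=[c.patient_id for c in cases[:18]]
    )
    return cfg, cases, ensemble


class TestDetector:
    def test_fold_assignment_partitions_training_patients(self, trained):
        _, _, ensemble = trained
        m = ensemble.manifest
        train_rows = m[m.role == "train"]
        assert set(train_rows.fold) == set(range(3))
        assert train_rows.patient_id.is_unique
        assert (m.loc[m.role == "test", "fold"] == -1).all()

    def test_no_leakage_between_test_and_folds(self, trained):
        _, _, ensemble = trained
        m = ensemble.manifest
        assert not set(m[m.role == "test"].patient_id) & set(
            m[m.role == "train"].patient_id
        )

    def test_heatmap_contrast_inside_lesions(self, trained):
        cfg, cases, ensemble = trained
        inside, outside = [], []
        for _, (vol, les) in zip(cases[18:], _detect_cohort(cfg, cases[18:])):
            heat = predict_heatmap(ensemble, vol)
            mask = les.labelmap > 0
            if mask.any():
                inside.append(heat.likelihood[mask].mean())
            outside.append(heat.likelihood[~mask].mean())
        assert np.mean(inside) > np.mean(outside)

    def test_heatmap_bounds_and_determinism(self, trained):
        cfg, cases, ensemble = trained
        vol, _ = _detect_cohort(cfg, cases[:1])[0]
        h1 = predict_heatmap(ensemble, vol)
        h2 = predict_heatmap(ensemble, vol)
        assert np.array_equal(h1.likelihood, h2.likelihood)
        assert h1.likelihood.min() >= 0 and h1.likelihood.max() <= 1

    def test_ensemble_of_identical_models_equals_single(self, trained):
        cfg, cases, ensemble = trained
        vol, _ = _detect_cohort(cfg, cases[:1])[0]
        single = predict_heatmap(ensemble.models[0], vol)
        repeated = predict_heatmap([ensemble.models[0]] * 3, vol)
        assert np.allclose(single.likelihood, repeated.likelihood)

    def test_all_zero_input_yields_finite_bounded_heatmap(self, trained):
        _, _, ensemble = trained
        vol = ImageVolume(np.zeros((64, 64, 8)), spacing=(1.5, 1.5, 4.0))
        heat = predict_heatmap(ensemble, vol)
        assert np.isfinite(heat.likelihood).all()

    def test_single_class_cohort_rejected(self, desk_phantom_config):
        import diagqm

        cfg = dataclasses.replace(desk_phantom_config, lesion_prevalence=0.0)
        cases = diagqm.generate_cohort(cfg, 6)
        with pytest.raises(ValueError):
            train_detector(_detect_cohort(cfg, cases), DetectTrainConfig())


class TestSurrogate:
    def test_constant_volume_gives_zero_evidence(self):
        vol = ImageVolume(np.full((32, 32, 4), 0.6), spacing=(1.0, 1.0, 3.0))
        heat = surrogate_detect(vol)
        assert not heat.likelihood.any()

    def test_global_maximum_inside_inserted_lesion(self):
        data = np.full((48, 48, 6), 0.8)
        xx, yy, zz = np.meshgrid(
            np.arange(48), np.arange(48), np.arange(6), indexing="ij"
        )
        lesion = ((xx - 24) ** 2 + (yy - 30) ** 2) / 16 + (zz - 3) ** 2 / 2 <= 1
        data[lesion] = 0.4
        heat = surrogate_detect(ImageVolume(data, spacing=(1.0, 1.0, 3.0)))
        peak = np.unravel_index(np.argmax(heat.likelihood), heat.likelihood.shape)
        assert lesion[peak]

    def test_response_monotone_in_lesion_contrast(self):
        def peak_for(drop):
            data = np.full((48, 48, 6), 0.8)
            data[20:28, 20:28, 2:4] = 0.8 * (1 - drop)
            params = SurrogateParams(contrast_scale=1.0)  # avoid saturation
            return surrogate_detect(
                ImageVolume(data, spacing=(1.0, 1.0, 3.0)), params
            ).likelihood.max()

        assert peak_for(0.15) < peak_for(0.30) < peak_for(0.45)
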