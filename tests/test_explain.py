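"""Grad-CAM saliency and its inverse-FFT time-domain mapping."""

import numpy as np
import pytest

from pediscreen.explain import (ClassActivationMap, cam_to_time, grad_cam,
                                render_overlay)
from pediscreen.model import preset, train_cv
from pediscreen.preprocess import SpectralTensor, build_input_tensor, tensorize, stack_tensors
from pediscreen.synth import (AbnormalitySpec, CohortSpec, generate_record,
                              inject_abnormality, normal_template,
                              sample_cohort)


@pytest.fixture(scope="module")
def trained_setup():
    """Small desk-scale ensemble trained on a mixed synthetic cohort."""
    records, manifest = sample_cohort(CohortSpec(n_records=160, seed=77))
    tensors, meta = tensorize(records)
    arch, tcfg = preset("desk", seed=5)
    tcfg.epochs = 3
    ensemble = train_cv(stack_tensors(tensors), meta,
                        manifest.abnormal_labels(),
                        list(manifest.table["patient_id"]), tcfg, arch)
    return ensemble, records, tensors, meta


class TestGradCam:
    def test_values_rectified_and_normalized(self, trained_setup):
        ensemble, _, tensors, meta = trained_setup
        cam = grad_cam(ensemble, tensors[0], meta[0])
        assert cam.values.shape == (12, 400)
        assert cam.values.min() >= 0.0
        assert cam.values.max() <= 1.0
        if cam.values.max() > 0:
            assert cam.values.max() == pytest.approx(1.0)

    @pytest.mark.parametrize("conv_index", [3, 12, 16])
    def test_output_shape_independent_of_layer_resolution(self, trained_setup,
                                                          conv_index):
        ensemble, _, tensors, meta = trained_setup
        cam = grad_cam(ensemble, tensors[1], meta[1], conv_index=conv_index)
        assert cam.values.shape == (12, 400)
        assert cam.conv_index == conv_index

    def test_conv_index_out_of_range(self, trained_setup):
        ensemble, _, tensors, meta = trained_setup
        with pytest.raises(ValueError, match="conv_index"):
            grad_cam(ensemble, tensors[0], meta[0], conv_index=40)

    def test_single_model_cam_matches_manual_chain(self, trained_setup):
        """CAM of one fold model equals the hand-computed weighted
        feature-map sum from that model's own activations/gradients."""
        from pediscreen.explain import _single_model_cam
        from pediscreen.model import normalize_inputs
        ensemble, _, tensors, meta = trained_setup
        model = ensemble.models()[0]
        X = tensors[0].values[None].astype(np.float32)
        amp, phase = normalize_inputs(X, ensemble.norm)
        m = np.asarray(meta[0], dtype=np.float32).reshape(1, -1)
        cam = _single_model_cam(model, amp, phase, m, conv_index=12)
        acts, grads = model.conv_activation_and_grad(12)
        weights = grads.mean(axis=(2, 3))
        expected = np.maximum((weights[:, :, None, None] * acts).sum(axis=1), 0)[0]
        np.testing.assert_allclose(cam, expected, atol=1e-7)


class TestCamToTime:
    def _tensor(self, L=3990, fs=500.0):
        # L/fs = 399/50 makes the native FFT grid coincide with the 400-bin
        # display grid, so resampling is exact
        B = int(np.floor(50.0 * L / fs)) + 1
        assert B == 400
        return SpectralTensor(
            values=np.zeros((2, 12, 400)), segment_length=L, fs=fs,
            lowpass_hz=50.0, n_bins_retained=B,
            amp_b=np.zeros((12, B)), phase_b=np.zeros((12, B)),
            record_id="toy")

    def test_zero_cam_gives_zero_heatmap(self):
        tensor = self._tensor()
        cam = ClassActivationMap(np.zeros((12, 400)), 12, "toy")
        heat = cam_to_time(cam, tensor)
        assert np.all(heat.values == 0.0)
        assert heat.values.shape == (12, tensor.segment_length)

    def test_single_bin_matches_rectified_cosine_envelope(self):
        tensor = self._tensor()
        j = 80                                  # 80 * 50/399 Hz
        f = j * 50.0 / 399.0
        cam_vals = np.zeros((12, 400))
        cam_vals[3, j] = 1.0
        heat = cam_to_time(ClassActivationMap(cam_vals, 12, "toy"), tensor)
        t = np.arange(tensor.segment_length) / tensor.fs
        w = int(round(0.040 * tensor.fs))
        expected = np.convolve(np.abs(np.cos(2 * np.pi * f * t)),
                               np.ones(w) / w, mode="same")
        expected = expected / expected.max()
        err = np.max(np.abs(heat.values[3] - expected)) / expected.max()
        assert err < 0.02
        assert np.all(heat.values[np.arange(12) != 3] < 1e-9)

    def test_linearity_before_normalization(self, rng):
        tensor = self._tensor()
        vals = rng.random((12, 400))
        phase = rng.uniform(-np.pi, np.pi, (12, 400))
        tensor.phase_b = phase
        h1 = cam_to_time(ClassActivationMap(vals, 12, "toy"), tensor,
                         normalize=False)
        h2 = cam_to_time(ClassActivationMap(2 * vals, 12, "toy"), tensor,
                         normalize=False)
        np.testing.assert_allclose(h2.values, 2 * h1.values, rtol=1e-9)

    def test_heatmap_length_matches_segments(self, trained_setup):
        ensemble, _, tensors, meta = trained_setup
        for i in range(0, 20):
            cam = grad_cam(ensemble, tensors[i], meta[i])
            heat = cam_to_time(cam, tensors[i])
            assert heat.values.shape == (12, tensors[i].segment_length)

    def test_record_mismatch_rejected(self, trained_setup):
        ensemble, _, tensors, meta = trained_setup
        cam = grad_cam(ensemble, tensors[0], meta[0])
        if tensors[1].record_id != tensors[0].record_id:
            with pytest.raises(ValueError):
                cam_to_time(cam, tensors[1])


class TestOverlay:
    def test_zero_heatmap_renders_plain_plot(self, trained_setup, tmp_path):
        _, records, tensors, _ = trained_setup
        from pediscreen.explain import TimeHeatmap
        heat = TimeHeatmap(np.zeros((12, tensors[0].segment_length)),
                           records[0].fs, records[0].record_id)
        path = render_overlay(records[0], heat, tmp_path / "plain.png")
        assert path.exists() and path.stat().st_size > 0

    def test_identical_inputs_identical_dimensions(self, trained_setup, tmp_path):
        import matplotlib.image as mpimg
        ensemble, records, tensors, meta = trained_setup
        cam = grad_cam(ensemble, tensors[0], meta[0])
        heat = cam_to_time(cam, tensors[0])
        p1 = render_overlay(records[0], heat, tmp_path / "a.png")
        p2 = render_overlay(records[0], heat, tmp_path / "b.png")
        assert mpimg.imread(p1).shape == mpimg.imread(p2).shape


class TestLocalization:
    def test_saliency_concentrates_in_qrs_for_rbbb(self, trained_setup):
        """On complete-RBBB records the model's saliency inside the true QRS
        windows (+/-60 ms) should exceed the record-wide mean for most
        records — a weak sanity check that the explanation points at the
        abnormal complex."""
        ensemble, _, _, _ = trained_setup
        rng = np.random.default_rng(13)
        hits, total = 0, 0
        for i in range(50):
            p = normal_template(90.0 * (1 + rng.uniform(-0.15, 0.15)))
            p.baseline_noise_sd = 0.02
            p = inject_abnormality(p, AbnormalitySpec("crbbb", 1.0))
            rec = generate_record(p, int(rng.integers(6, 19)), "male",
                                  seed=int(rng.integers(2**31)),
                                  record_id=f"rbbb{i}", findings={"crbbb"})
            tensor, meta = build_input_tensor(rec)
            cam = grad_cam(ensemble, tensor, meta)
            heat = cam_to_time(cam, tensor)
            # QRS windows relative to the extracted segment
            from pediscreen.preprocess import detect_qrs
            ann = detect_qrs(rec)
            start = ann.r_sample_indices[1]
            pad = int(0.060 * rec.fs)
            mask = np.zeros(tensor.segment_length, dtype=bool)
            for a, b in rec.qrs_windows:
                lo = max(0, a - pad - start)
                hi = min(tensor.segment_length, b + pad - start)
                if hi > lo:
                    mask[lo:hi] = True
            if not mask.any() or mask.all():
                continue
            sal = heat.values.mean(axis=0)
            total += 1
            if sal[mask].mean() > sal.mean():
                hits += 1
        assert total >= 40
        assert hits / total >= 0.70
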