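"""Frequency-domain grad-CAM mapped back to time-domain ECG saliency.

Grad-CAM is computed at a chosen convolutional layer (default: the 12th,
counting the amplitude stem then the trunk): channel weights are the
spatial mean of the abnormality-logit gradients, the weighted feature-map
sum is rectified and bilinearly upsampled to the 12 x 400 tensor grid. The
map is then read as a surrogate amplitude spectrum per lead: resampled
from the 400-bin grid back to the record's native retained-frequency grid,
combined with the record's original phase spectrum, and inverted by real
FFT to a per-lead, per-sample saliency trace over the analyzed segment,
which can be rendered under the Cabrera-ordered waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy import ndimage

from .io import ECGRecord
from .model import Ensemble, normalize_inputs
from .nnet import SpectralConvNet
from .preprocess import (PreprocessConfig, SpectralTensor, cabrera_reorder,
                         detect_qrs, extract_segment, inverse_spectral)


@dataclass
class ClassActivationMap:
    """Non-negative 12 x 400 saliency on the spectral grid, max <= 1."""

    values: np.ndarray
    conv_index: int
    record_id: str


@dataclass
class TimeHeatmap:
    """Per-lead (Cabrera order) saliency over the analyzed segment."""

    values: np.ndarray          # (12, L), in [0, 1]
    fs: float
    record_id: str


def _single_model_cam(model: SpectralConvNet, amp: np.ndarray, phase: np.ndarray,
                      meta: np.ndarray, conv_index: int) -> np.ndarray:
    if not (1 <= conv_index <= model.n_conv_layers):
        raise ValueError(
            f"conv_index {conv_index} outside 1..{model.n_conv_layers}")
    # dropout must not perturb the saliency pass
    rates = []
    for layer in model.head:
        if hasattr(layer, "rate"):
            rates.append(layer.rate)
            layer.rate = 0.0
    try:
        model.forward(amp, phase, meta, train=True)
        model.backward(np.ones(amp.shape[0], dtype=np.float32))
    finally:
        it = iter(rates)
        for layer in model.head:
            if hasattr(layer, "rate"):
                layer.rate = next(it)
    acts, grads = model.conv_activation_and_grad(conv_index)
    weights = grads.mean(axis=(2, 3))                      # (N, C)
    cam = np.maximum((weights[:, :, None, None] * acts).sum(axis=1), 0.0)
    return cam[0]


def grad_cam(handle: Union[Ensemble, SpectralConvNet],
             tensor: Union[SpectralTensor, np.ndarray],
             meta: np.ndarray, conv_index: Optional[int] = None,
             out_shape: tuple[int, int] = (12, 400)) -> ClassActivationMap:
    """Gradient-weighted class activation map for one record.

    With an :class:`~pediscreen.model.Ensemble`, inputs are normalized with
    the ensemble's training statistics and the CAMs of the five fold
    models are averaged. The map is bilinearly upsampled from the target
    layer's (lead x frequency) resolution to ``out_shape`` and
    max-normalized to 1 when any activation survives the rectifier.
    """
    record_id = tensor.record_id if isinstance(tensor, SpectralTensor) else ""
    values = tensor.values if isinstance(tensor, SpectralTensor) else np.asarray(tensor)
    X = values[None].astype(np.float32)
    meta = np.asarray(meta, dtype=np.float32).reshape(1, -1)

    if isinstance(handle, Ensemble):
        if conv_index is None:
            conv_index = handle.arch.grad_cam_conv_index
        amp, phase = normalize_inputs(X, handle.norm) if handle.norm else (X[:, 0], X[:, 1])
        cams = [_single_model_cam(m, amp, phase, meta, conv_index)
                for m in handle.models()]
        shapes = {c.shape for c in cams}
        assert len(shapes) == 1
        cam = np.mean(cams, axis=0)
    else:
        if conv_index is None:
            conv_index = 12
        cam = _single_model_cam(handle, X[:, 0], X[:, 1], meta, conv_index)

    zoom = (out_shape[0] / cam.shape[0], out_shape[1] / cam.shape[1])
    cam = ndimage.zoom(cam, zoom, order=1, grid_mode=True, mode="nearest")
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return ClassActivationMap(values=cam, conv_index=conv_index, record_id=record_id)


def cam_to_time(cam: ClassActivationMap, tensor: SpectralTensor,
                smooth_ms: float = 40.0, normalize: bool = True) -> TimeHeatmap:
    """Carry a spectral CAM back to the time domain.

    Each lead row is resampled from the 400-bin display grid to the
    record's retained B-bin FFT grid (the inverse of the resize mapping),
    combined with the record's original phase, and inverted by real FFT to
    the segment length L. Saliency is the absolute value, smoothed by a
    ``smooth_ms`` moving average and (optionally) max-normalized per
    record. Linear in the CAM up to the final normalization.
    """
    if cam.record_id and tensor.record_id and cam.record_id != tensor.record_id:
        raise ValueError(
            f"CAM belongs to {cam.record_id!r}, tensor to {tensor.record_id!r}")
    L, fs, B = tensor.segment_length, tensor.fs, tensor.n_bins_retained
    target_grid = np.linspace(0.0, tensor.lowpass_hz, cam.values.shape[1])
    src_freqs = np.arange(B) * fs / L
    amp_b = np.stack([np.interp(src_freqs, target_grid, row) for row in cam.values])
    sal = inverse_spectral(amp_b, tensor.phase_b, L, fs)
    sal = np.abs(sal)
    w = max(1, int(round(smooth_ms / 1000.0 * fs)))
    kernel = np.ones(w) / w
    sal = np.stack([np.convolve(row, kernel, mode="same") for row in sal])
    if normalize:
        peak = sal.max()
        if peak > 0:
            sal = sal / peak
    return TimeHeatmap(values=sal, fs=fs, record_id=tensor.record_id)


def render_overlay(record: ECGRecord, heatmap: TimeHeatmap, path,
                   cfg: Optional[PreprocessConfig] = None) -> Path:
    """Cabrera-ordered 12-row ECG plot with saliency as background color."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    cfg = (cfg or PreprocessConfig()).validate()
    ann = detect_qrs(record, cfg)
    seg = extract_segment(record, ann)
    mat = cabrera_reorder(seg.leads, cfg.cabrera_order)
    if mat.shape[1] != heatmap.values.shape[1]:
        raise ValueError(
            f"heatmap length {heatmap.values.shape[1]} does not match the "
            f"record's segment length {mat.shape[1]}")
    t = np.arange(mat.shape[1]) / seg.fs
    fig, axes = plt.subplots(12, 1, figsize=(10, 14), sharex=True)
    for i, (ax, name) in enumerate(zip(axes, cfg.cabrera_order)):
        lo = float(mat[i].min()) - 0.2
        hi = float(mat[i].max()) + 0.2
        ax.imshow(heatmap.values[i][None, :], aspect="auto",
                  extent=(0, t[-1], lo, hi), origin="lower",
                  cmap="YlOrRd", vmin=0.0, vmax=1.0, alpha=0.8)
        ax.plot(t, mat[i], color="black", linewidth=0.7)
        ax.set_ylabel(name, rotation=0, labelpad=18, va="center")
        ax.set_yticks([])
    axes[-1].set_xlabel("time (s)")
    fig.suptitle(f"{record.record_id}: model saliency overlay")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
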