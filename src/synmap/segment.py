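"""Background subtraction and synapse segmentation.

The built-in segmenter is a fully deterministic classical pipeline (Gaussian
smoothing, Otsu threshold, hole filling, size pruning, distance-transform
watershed) whose every parameter is a pinned function of the expected synapse
diameter. External deep-learning backends (e.g. a Cellpose install) plug in
through the adapter registry: any callable ``(image_2d, diameter_px) ->
integer label grid of the same shape`` honors the contract.

Segmentation follows the resize-for-inference contract: images are shrunk by
``pre_inference_scale`` (bilinear), the diameter is scaled alongside so the
same physical size is targeted, and the resulting mask is mapped back to the
original shape by nearest-neighbor so labels stay integral.
"""

from __future__ import annotations

import logging
import math
from typing import Callable, Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import watershed
from skimage.transform import resize

from .config import AnalysisConfig
from .core import MIN_IMAGE_DIM, ChannelImage, FieldOfView, LabelMask

logger = logging.getLogger(__name__)

SegmenterBackend = Callable[[np.ndarray, float], np.ndarray]

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


# ---------------------------------------------------------------------------
# Background subtraction
# ---------------------------------------------------------------------------

def estimate_background(pixels: np.ndarray, outside: Optional[np.ndarray] = None) -> float:
    """Scalar background estimate for one channel.

    With a mask available, the background is the median of pixels outside all
    labels. Before any mask exists, it falls back to the median of the
    lowest-intensity 25% of pixels, which is robust as long as cells cover
    less than ~75% of the field.
    """
    flat = np.asarray(pixels, dtype=float).ravel()
    if outside is not None:
        vals = np.asarray(pixels, dtype=float)[outside]
        if vals.size == 0:
            vals = flat
    else:
        k = max(1, flat.size // 4)
        vals = np.partition(flat, k - 1)[:k]
    return float(np.median(vals))


def subtract_background(
    field: FieldOfView, mask: Optional[LabelMask] = None
) -> tuple[FieldOfView, dict[str, float]]:
    """Subtract a per-channel scalar background estimate, clipping at zero.

    Returns the corrected field and the per-channel estimates (recorded in
    the run manifest for audit). An all-zero channel yields b = 0 and is
    returned unchanged.
    """
    outside = None if mask is None else mask.labels == 0
    backgrounds: dict[str, float] = {}
    channels = []
    for ch in field.channels:
        b = estimate_background(ch.pixels, outside)
        backgrounds[ch.name] = b
        channels.append(
            ChannelImage(np.clip(ch.pixels.astype(float) - b, 0.0, None), ch.name, ch.pixel_size_um)
        )
    return (
        FieldOfView(channels, field.condition, field.replicate, field.source_path, field.fov_id),
        backgrounds,
    )


# ---------------------------------------------------------------------------
# Resize-for-inference contract
# ---------------------------------------------------------------------------

def rescale_for_inference(
    image: np.ndarray, scale: float, diameter_px: float
) -> tuple[np.ndarray, float]:
    """Shrink an image for inference and adjust the target diameter to match.

    Output dimensions are ``round(input * scale)``; interpolation is bilinear.
    The adjusted diameter is ``diameter_px * scale`` so the backend still
    targets the same physical object size.
    """
    if not (0.3 <= scale <= 1.0):
        raise ValueError(f"pre-inference scale must be in [0.3, 1.0], got {scale}")
    if scale == 1.0:
        return np.asarray(image, dtype=float), float(diameter_px)
    h, w = image.shape
    out_shape = (int(round(h * scale)), int(round(w * scale)))
    if min(out_shape) < MIN_IMAGE_DIM:
        raise ValueError(f"resized image {out_shape} smaller than {MIN_IMAGE_DIM} px — scale {scale} too small")
    resized = resize(
        np.asarray(image, dtype=float), out_shape, order=1, preserve_range=True,
        anti_aliasing=False,
    )
    return resized, float(diameter_px) * scale


def upsample_mask(labels: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Map a label grid back to the original shape by nearest-neighbor."""
    if labels.shape == tuple(out_shape):
        return labels
    up = resize(labels, out_shape, order=0, preserve_range=True, anti_aliasing=False)
    return np.rint(up).astype(np.int32)


# ---------------------------------------------------------------------------
# Built-in segmenter
# ---------------------------------------------------------------------------

def _relabel_raster_order(labels: np.ndarray) -> np.ndarray:
    """Relabel to {1..n} by raster-scan order of first occurrence (deterministic)."""
    flat = labels.ravel()
    fg = flat[flat > 0]
    if fg.size == 0:
        return np.zeros_like(labels, dtype=np.int32)
    uniq, first = np.unique(fg, return_index=True)
    order = uniq[np.argsort(first)]
    lut = np.zeros(int(flat.max()) + 1, dtype=np.int32)
    lut[order] = np.arange(1, order.size + 1, dtype=np.int32)
    return lut[labels]


def segment_builtin(image: np.ndarray, diameter_px: float) -> np.ndarray:
    """Deterministic classical segmentation of disk-like synapses.

    Pipeline (all parameters pinned to ``diameter_px``): Gaussian smoothing
    with sigma = diameter/20; Otsu threshold on the smoothed image;
    morphological hole filling; removal of objects with area below
    pi*(diameter/4)^2/4; watershed splitting of touching objects on the
    negated distance transform, seeded at distance maxima separated by at
    least diameter/2; relabeling to {1..n}. A blank image yields no labels.
    """
    img = np.asarray(image, dtype=float)
    if img.max() <= img.min():
        return np.zeros(img.shape, dtype=np.int32)
    sigma = diameter_px / 20.0
    smoothed = gaussian(img, sigma=sigma, preserve_range=True)
    thr = threshold_otsu(smoothed)
    binary = smoothed > thr
    binary = ndi.binary_fill_holes(binary)
    # prune objects with area < pi*(diameter/4)^2/4 (strict inequality)
    min_area = math.pi * (diameter_px / 4.0) ** 2 / 4.0
    comp, n_comp = ndi.label(binary, structure=_FOUR_CONN)
    if n_comp:
        areas = np.bincount(comp.ravel())
        keep = np.zeros(n_comp + 1, dtype=bool)
        keep[1:] = areas[1:] >= min_area
        binary = keep[comp]
    if not binary.any():
        return np.zeros(img.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(binary)
    min_sep = max(1, int(round(diameter_px / 2.0)))
    coords = peak_local_max(dist, min_distance=min_sep, labels=binary, exclude_border=False)
    if coords.size == 0:
        coords = np.array([np.unravel_index(np.argmax(dist), dist.shape)])
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    labels = watershed(-dist, markers, mask=binary, connectivity=1)
    return _relabel_raster_order(labels)


# ---------------------------------------------------------------------------
# Backend registry and the full segmentation stage
# ---------------------------------------------------------------------------

BACKENDS: dict[str, SegmenterBackend] = {"builtin": segment_builtin}


def register_backend(name: str, fn: SegmenterBackend) -> None:
    """Register an external segmenter adapter under a config `backend` key."""
    BACKENDS[name] = fn


def segment(
    field: FieldOfView,
    config: AnalysisConfig,
    backend: Optional[SegmenterBackend] = None,
) -> LabelMask:
    """Segment the configured channel of a field into a LabelMask.

    Applies the resize-for-inference contract, invokes the backend at the
    adjusted diameter, maps labels back to the original resolution and
    normalizes them to {1..n}. Deterministic for the builtin backend.
    """
    if backend is None:
        try:
            backend = BACKENDS[config.backend]
        except KeyError:
            raise RuntimeError(
                f"segmentation backend {config.backend!r} is not available; "
                f"registered: {sorted(BACKENDS)}. Use backend='builtin' or "
                f"register an adapter with synmap.segment.register_backend."
            ) from None
    img = field.channel(config.segmentation_channel).pixels
    resized, adj_diam = rescale_for_inference(img, config.pre_inference_scale, config.diameter_px)
    labels_small = backend(resized, adj_diam)
    if labels_small.shape != resized.shape:
        raise RuntimeError(
            f"backend {config.backend!r} returned shape {labels_small.shape}, expected {resized.shape}"
        )
    labels = upsample_mask(np.asarray(labels_small, dtype=np.int32), img.shape)
    if config.exclude_border_cells:
        border = np.zeros(labels.shape, dtype=bool)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        for lab in np.unique(labels[border]):
            if lab > 0:
                labels[labels == lab] = 0
    labels = _relabel_raster_order(labels)
    return LabelMask(labels=labels, seg_channel=config.segmentation_channel, backend_used=config.backend)
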