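"""Radial averaging of segmented synapses.

The ring-replacement operator maps each pixel in a cell's bounding box to the
mean intensity of all pixels at the same integer radius from the synapse
center, producing a rotationally symmetric image and a 1D radius-vs-intensity
profile. Because rings partition the bounding box, ring means are conserved
and the operator is exactly invariant to 90-degree rotations about the
center.

Conventions: the center is the cell's binary-mask centroid rounded to the
nearest pixel; radii are Euclidean distances rounded to the nearest integer
(symmetric bins around integer radii); by default means run over ALL
bounding-box pixels ("bounding box" mode), with a mask-only mode available
for sensitivity analysis.

Profiles can be rescaled to a common target length by linear interpolation
("scaled" mode, removing segmentation-size effects) or left at native length
("unscaled", reflecting absolute spatial extent).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .core import LabelMask, ProfileEnsemble, RadialAverageImage, RadialProfile

logger = logging.getLogger(__name__)


def mask_center(mask: LabelMask, cell_id: int) -> tuple[int, int]:
    """Binary-mask centroid of one cell, rounded to the nearest pixel."""
    rr, cc = np.nonzero(mask.labels == cell_id)
    if rr.size == 0:
        raise KeyError(f"cell {cell_id} not present in mask")
    return int(np.rint(rr.mean())), int(np.rint(cc.mean()))


def radial_average(
    image: np.ndarray,
    mask: LabelMask,
    cell_id: int,
    mask_only: bool = False,
) -> tuple[RadialAverageImage, RadialProfile]:
    """Ring-replacement radial average of one cell.

    Every bounding-box pixel is replaced by the mean ORIGINAL intensity of
    the pixels sharing its integer radius from the cell center; the profile
    holds those means per radius bin (bins with no pixels are NaN with count
    0). In ``mask_only`` mode the means are taken over mask pixels only.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != mask.labels.shape:
        raise ValueError("image and mask shapes differ")
    binary = mask.labels == cell_id
    if not binary.any():
        raise KeyError(f"cell {cell_id} not present in mask")
    cr, cc_ = mask_center(mask, cell_id)
    rows, cols = np.nonzero(binary)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    sub = image[r0:r1, c0:c1]
    sub_mask = binary[r0:r1, c0:c1]
    gr, gc = np.mgrid[r0:r1, c0:c1]
    radii = np.rint(np.hypot(gr - cr, gc - cc_)).astype(int)
    select = sub_mask if mask_only else np.ones_like(sub_mask)
    n_bins = int(radii[select].max()) + 1
    counts = np.bincount(radii[select], minlength=n_bins).astype(float)
    sums = np.bincount(radii[select], weights=sub[select], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    out = np.where(radii < n_bins, means[np.clip(radii, 0, n_bins - 1)], np.nan)
    if mask_only:
        out = np.nan_to_num(out, nan=0.0)
    rad_img = RadialAverageImage(
        pixels=out, center=(cr, cc_), bbox=(int(r0), int(c0), int(r1), int(c1)),
        max_radius_px=n_bins - 1,
    )
    profile = RadialProfile(values=means, counts=counts, scaled=False)
    return rad_img, profile


def scale_profile(profile: RadialProfile, target_length: int) -> RadialProfile:
    """Resample a profile onto ``target_length`` bins spanning [0, R].

    Linear interpolation; empty (NaN) bins are bridged from their finite
    neighbors. Endpoints are preserved exactly, and monotone profiles stay
    monotone.
    """
    if profile.length < 2:
        raise ValueError("cannot scale a profile with fewer than 2 bins")
    if target_length < 2:
        raise ValueError("target length must be >= 2")
    x_old = np.arange(profile.length, dtype=float)
    x_new = np.linspace(0.0, profile.length - 1.0, target_length)
    finite = np.isfinite(profile.values)
    if not finite.any():
        raise ValueError("profile has no finite values")
    values = np.interp(x_new, x_old[finite], profile.values[finite])
    counts = np.interp(x_new, x_old, profile.counts)
    return RadialProfile(values=values, counts=counts, scaled=True)


def aggregate_profiles(
    profiles: Sequence[RadialProfile], normalize: bool = False
) -> ProfileEnsemble:
    """Per-bin mean and SEM over a group of profiles.

    Scaled profiles must share one length; unscaled profiles are padded with
    missing values beyond each cell's own maximum radius, so per-bin n
    shrinks with radius. SEM is the sample (n-1) standard deviation divided
    by sqrt(n per bin). With ``normalize``, the mean profile is divided by
    its own maximum (peak = 1) and the SEM is scaled by the same factor.
    """
    if len(profiles) == 0:
        empty = np.array([])
        return ProfileEnsemble(mean=empty, sem=empty, n_per_bin=empty, n_cells=0, normalized=normalize)
    max_len = max(p.length for p in profiles)
    stack = np.full((len(profiles), max_len), np.nan)
    for i, p in enumerate(profiles):
        stack[i, : p.length] = p.values
    n = np.sum(np.isfinite(stack), axis=0)
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # ddof with n=1 bins
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
        sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    if normalize:
        peak = np.nanmax(mean)
        if peak > 0:
            mean = mean / peak
            sem = sem / peak
    return ProfileEnsemble(mean=mean, sem=sem, n_per_bin=n.astype(float), n_cells=len(profiles), normalized=normalize)


# ---------------------------------------------------------------------------
# Group TIFF outputs
# ---------------------------------------------------------------------------

def _pad_centered(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=np.float32)
    h, w = img.shape
    r0 = (shape[0] - h) // 2
    c0 = (shape[1] - w) // 2
    out[r0: r0 + h, c0: c0 + w] = img
    return out


def build_group_outputs(
    radial_images: Sequence[RadialAverageImage],
    channel: str,
    out_dir: Path | str,
) -> dict[str, Path]:
    """Write the three per-group radial TIFFs for one channel.

    ``<Channel>_radMontage.tif``: all radial-averaged synapses tiled in a
    ceil(sqrt(n)) x ceil(n/ceil(sqrt(n))) grid for visual inspection;
    ``<Channel>_radStack.tif``: one plane per cell, in input order;
    ``<Channel>_radTotAv.tif``: the per-pixel mean over the padded stack.
    Images are zero-padded and centered to the largest bounding box.
    """
    out_dir = Path(out_dir)
    if len(radial_images) == 0:
        logger.warning("no radial images for channel %s; group outputs skipped", channel)
        return {}
    out_dir.mkdir(parents=True, exist_ok=True)
    max_h = max(im.pixels.shape[0] for im in radial_images)
    max_w = max(im.pixels.shape[1] for im in radial_images)
    stack = np.stack(
        [_pad_centered(np.nan_to_num(im.pixels, nan=0.0), (max_h, max_w)) for im in radial_images]
    ).astype(np.float32)
    n = stack.shape[0]
    nrows = int(math.ceil(math.sqrt(n)))
    ncols = int(math.ceil(n / nrows))
    montage = np.zeros((nrows * max_h, ncols * max_w), dtype=np.float32)
    for i in range(n):
        r, c = divmod(i, ncols)
        montage[r * max_h: (r + 1) * max_h, c * max_w: (c + 1) * max_w] = stack[i]
    totav = stack.mean(axis=0)
    paths = {
        "montage": out_dir / f"{channel}_radMontage.tif",
        "stack": out_dir / f"{channel}_radStack.tif",
        "totav": out_dir / f"{channel}_radTotAv.tif",
    }
    tifffile.imwrite(paths["montage"], montage, photometric="minisblack")
    tifffile.imwrite(paths["stack"], stack, photometric="minisblack")
    tifffile.imwrite(paths["totav"], totav, photometric="minisblack")
    return paths
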