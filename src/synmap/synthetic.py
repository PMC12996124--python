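"""Synthetic synapse image generator with exact ground truth.

Emulates TIRF fields of T-cell synapses on a supported lipid bilayer: each
cell is a disk whose channels put weight on three concentric domains — a
central disk (cSMAC-like, radius fraction ``f_c``), an intermediate annulus
(pSMAC-like, fractions ``[f_c, f_p]``) and a distal annulus (corolla-like,
``[f_p, 1]``). Domain edges are Gaussian-smoothed (sigma 2 px) to avoid
rasterization artifacts in circularity and profile-peak measurements.

Channel enrichment is parameterized as the realized mask-mean fold over
background: the domain amplitude is calibrated per synapse so that the
noise-free mean intensity under the ground-truth mask equals
``fold x background`` exactly, despite edge smoothing. Channels with no
domain weight are spatially flat (free ligand on the bilayer) and carry only
background plus noise; designated channel pairs share Gaussian noise with a
chosen correlation ``rho``, so the expected within-mask Pearson coefficient
of a flat pair is exactly ``rho``.

Datasets are written in the condition-subfolder layout the analysis pipeline
discovers, alongside a ``ground_truth.csv`` keyed by (condition, fov, cell).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from . import radial
from .core import ChannelImage, FieldOfView, LabelMask
from .io import write_field

logger = logging.getLogger(__name__)

EDGE_SIGMA = 2.0
MIN_GAP_PX = 10
MAX_PLACEMENT_TRIES = 1000


@dataclass
class ChannelModel:
    """How one channel distributes over the synapse domains.

    ``weights`` are the (cSMAC, pSMAC, dSMAC) domain weights; all-zero means
    a spatially flat channel. ``fold`` is the target mask-mean enrichment
    over background (1.0 = no enrichment). ``noise_sd`` is the additive
    Gaussian noise standard deviation in intensity units.
    """

    name: str
    weights: tuple[float, float, float] = (0.0, 0.0, 0.0)
    fold: float = 1.0
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.fold <= 0:
            raise ValueError("fold must be positive")


@dataclass
class SynapseSpec:
    """Ground-truth parameters for one synthetic synapse."""

    radius_px: float
    channels: list[ChannelModel]
    center: tuple[int, int] = (0, 0)
    f_c: float = 0.3
    f_p: float = 0.8
    background: float = 100.0
    rho: Optional[float] = None
    rho_pair: Optional[tuple[str, str]] = None

    def __post_init__(self) -> None:
        if self.radius_px < 8:
            raise ValueError("synapse radius must be >= 8 px")
        if not (0.0 < self.f_c < self.f_p < 1.0):
            raise ValueError(f"need 0 < f_c < f_p < 1, got f_c={self.f_c}, f_p={self.f_p}")
        if self.rho is not None and not (-1.0 <= self.rho <= 1.0):
            raise ValueError("rho must be in [-1, 1]")


@dataclass
class ConditionSpec:
    """One experimental condition of a synthetic dataset."""

    label: str
    n_fields: int
    cells_per_field: int
    channels: list[ChannelModel]
    rho: Optional[float] = None
    rho_pair: Optional[tuple[str, str]] = None
    field_shape: tuple[int, int] = (512, 512)
    radius_range: tuple[float, float] = (40.0, 55.0)
    f_c: float = 0.3
    f_p: float = 0.8
    background: float = 100.0
    n_replicates: int = 3


def default_channels() -> list[ChannelModel]:
    """The standard five-channel panel used throughout tests and examples.

    "actin" covers the whole contact (segmentation channel), "tcr" the
    central domain, "cd2" the distal corolla ring; "ligA"/"ligB" are flat
    bilayer ligands whose noise can be correlated at a chosen rho.
    """
    return [
        ChannelModel("actin", (1.0, 1.0, 1.0), fold=3.0, noise_sd=20.0),
        ChannelModel("tcr", (1.0, 0.0, 0.0), fold=3.0, noise_sd=10.0),
        ChannelModel("cd2", (0.0, 0.0, 1.0), fold=3.0, noise_sd=10.0),
        ChannelModel("ligA", fold=1.0, noise_sd=10.0),
        ChannelModel("ligB", fold=1.0, noise_sd=10.0),
    ]


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _pad_for(radius: float) -> int:
    return int(math.ceil(3 * EDGE_SIGMA)) + 2


def _domain_maps(
    shape: tuple[int, int], center: tuple[int, int], radius: float, f_c: float, f_p: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Smoothed indicator maps of the three domains plus the binary mask."""
    rr, cc = np.mgrid[0: shape[0], 0: shape[1]]
    dist = np.hypot(rr - center[0], cc - center[1])
    mask = dist <= radius
    ind_c = (dist <= f_c * radius).astype(float)
    ind_p = ((dist > f_c * radius) & (dist <= f_p * radius)).astype(float)
    ind_d = ((dist > f_p * radius) & (dist <= radius)).astype(float)
    smooth = lambda a: ndi.gaussian_filter(a, EDGE_SIGMA)  # noqa: E731
    return smooth(ind_c), smooth(ind_p), smooth(ind_d), mask


def _channel_signal(
    ch: ChannelModel,
    maps: tuple[np.ndarray, np.ndarray, np.ndarray],
    mask: np.ndarray,
    background: float,
) -> tuple[np.ndarray, float]:
    """Noise-free above-background signal and its calibrated amplitude."""
    w = ch.weights[0] * maps[0] + ch.weights[1] * maps[1] + ch.weights[2] * maps[2]
    mbar = float(w[mask].mean()) if mask.any() else 0.0
    if ch.fold == 1.0 or mbar == 0.0:
        if ch.fold != 1.0:
            logger.warning("channel %s: no domain weight under mask, fold ignored", ch.name)
        return np.zeros_like(w), 0.0
    amplitude = background * (ch.fold - 1.0) / mbar
    return amplitude * w, amplitude


def correlated_pair(
    shape: tuple[int, int], rho: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two standardized Gaussian fields with expected Pearson correlation rho.

    B = rho*Z_A + sqrt(1 - rho^2)*Z_B on independent standard normals, so at
    rho = 1 the fields coincide and at rho = 0 they are independent.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must be in [-1, 1]")
    z_a = rng.standard_normal(shape)
    z_b = rng.standard_normal(shape)
    return z_a, rho * z_a + math.sqrt(1.0 - rho**2) * z_b


# ---------------------------------------------------------------------------
# Single-synapse rendering
# ---------------------------------------------------------------------------

def render_synapse(
    spec: SynapseSpec, rng_seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Render one synapse on its own tile.

    Returns ``(tile, mask, truth)``: the tile is a (C, H, W) stack of
    background + calibrated domain signal + Gaussian noise, clipped at 0;
    the mask is the ground-truth disk; the truth dict records center,
    radius, per-channel expected MFI and fold change, and the expected
    radial profile peak (bin of the noise-free profile argmax and the
    profile length, for conversion to any target length).
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    pad = _pad_for(spec.radius_px)
    half = int(math.ceil(spec.radius_px)) + pad
    side = 2 * half + 1
    center = (half, half)
    mc, mp, md, mask = _domain_maps((side, side), center, spec.radius_px, spec.f_c, spec.f_p)
    noises = _make_noise_fields(spec.channels, (side, side), spec.rho, spec.rho_pair, rng)
    planes = []
    truth: dict = {
        "center": center,
        "radius_px": spec.radius_px,
        "area_px": int(mask.sum()),
        "channels": {},
    }
    gt_mask = LabelMask(mask.astype(np.int32))
    for ch in spec.channels:
        signal, amplitude = _channel_signal(ch, (mc, mp, md), mask, spec.background)
        noiseless = spec.background + signal
        plane = np.clip(noiseless + ch.noise_sd * noises[ch.name], 0.0, None)
        planes.append(plane)
        _, prof = radial.radial_average(noiseless, gt_mask, 1)
        peak_bin = int(np.nanargmax(prof.values))
        truth["channels"][ch.name] = {
            "expected_mfi": float(noiseless[mask].mean()),
            "expected_fold": ch.fold,
            "amplitude": amplitude,
            "peak_radius_px": peak_bin,
            "profile_length": prof.length,
        }
    return np.stack(planes), mask, truth


def _make_noise_fields(
    channels: Sequence[ChannelModel],
    shape: tuple[int, int],
    rho: Optional[float],
    rho_pair: Optional[tuple[str, str]],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Standardized noise field per channel, correlated for the rho pair."""
    fields: dict[str, np.ndarray] = {}
    pair_done = False
    for ch in channels:
        if rho_pair is not None and rho is not None and ch.name in rho_pair:
            if not pair_done:
                a, b = correlated_pair(shape, rho, rng)
                fields[rho_pair[0]], fields[rho_pair[1]] = a, b
                pair_done = True
        else:
            fields[ch.name] = rng.standard_normal(shape)
    for ch in channels:  # pair channels not in list order still need entries
        if ch.name not in fields:
            fields[ch.name] = rng.standard_normal(shape)
    return fields


# ---------------------------------------------------------------------------
# Field and dataset generation
# ---------------------------------------------------------------------------

def _place_cells(
    shape: tuple[int, int],
    radii: Sequence[float],
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Non-overlapping centers by rejection sampling (min edge gap 10 px)."""
    centers: list[tuple[int, int]] = []
    placed_r: list[float] = []
    for r in radii:
        margin = int(math.ceil(r)) + _pad_for(r)
        ok = False
        for _ in range(MAX_PLACEMENT_TRIES):
            cr = int(rng.integers(margin, shape[0] - margin))
            cc = int(rng.integers(margin, shape[1] - margin))
            if all(
                math.hypot(cr - pr, cc - pc) >= r + pr_r + MIN_GAP_PX
                for (pr, pc), pr_r in zip(centers, placed_r)
            ):
                centers.append((cr, cc))
                placed_r.append(r)
                ok = True
                break
        if not ok:
            logger.warning("placement failed after %d tries; field has %d cells", MAX_PLACEMENT_TRIES, len(centers))
            break
    return centers


def truth_mask(shape: tuple[int, int], centers: Sequence[tuple[int, int]], radii: Sequence[float]) -> LabelMask:
    """Ground-truth label mask of disks, labeled 1..n in the given order."""
    rr, cc = np.mgrid[0: shape[0], 0: shape[1]]
    labels = np.zeros(shape, dtype=np.int32)
    for i, ((r0, c0), rad) in enumerate(zip(centers, radii), start=1):
        labels[np.hypot(rr - r0, cc - c0) <= rad] = i
    return LabelMask(labels)


def generate_field(
    cond: ConditionSpec, rng: np.random.Generator, fov_index: int
) -> tuple[FieldOfView, pd.DataFrame]:
    """Render one multi-channel field of a condition plus its truth table."""
    shape = cond.field_shape
    radii = [float(rng.uniform(*cond.radius_range)) for _ in range(cond.cells_per_field)]
    centers = _place_cells(shape, radii, rng)
    radii = radii[: len(centers)]
    order = sorted(range(len(centers)), key=lambda i: centers[i])
    centers = [centers[i] for i in order]
    radii = [radii[i] for i in order]

    signal = {ch.name: np.zeros(shape) for ch in cond.channels}
    truth_rows = []
    for cell_idx, (center, r) in enumerate(zip(centers, radii), start=1):
        half = int(math.ceil(r)) + _pad_for(r)
        r0, c0 = center[0] - half, center[1] - half
        r1, c1 = center[0] + half + 1, center[1] + half + 1
        win_shape = (r1 - r0, c1 - c0)
        win_center = (center[0] - r0, center[1] - c0)
        mc, mp, md, mask = _domain_maps(win_shape, win_center, r, cond.f_c, cond.f_p)
        gt_mask = LabelMask(mask.astype(np.int32))
        row: dict = {
            "cell": cell_idx,
            "center_row": center[0],
            "center_col": center[1],
            "radius_px": r,
            "area_px": int(mask.sum()),
            "equiv_diameter_px": 2.0 * math.sqrt(mask.sum() / math.pi),
            "rho": np.nan if cond.rho is None else cond.rho,
        }
        for ch in cond.channels:
            s, amplitude = _channel_signal(ch, (mc, mp, md), mask, cond.background)
            signal[ch.name][r0:r1, c0:c1] += s
            noiseless = cond.background + s
            _, prof = radial.radial_average(noiseless, gt_mask, 1)
            row[f"mfi_{ch.name}"] = float(noiseless[mask].mean())
            row[f"fold_{ch.name}"] = ch.fold
            row[f"peak_radius_{ch.name}"] = int(np.nanargmax(prof.values))
            row[f"profile_len_{ch.name}"] = prof.length
        truth_rows.append(row)

    noises = _make_noise_fields(cond.channels, shape, cond.rho, cond.rho_pair, rng)
    channels = []
    for ch in cond.channels:
        plane = np.clip(
            cond.background + signal[ch.name] + ch.noise_sd * noises[ch.name], 0.0, None
        ).astype(np.float32)
        channels.append(ChannelImage(plane, ch.name))
    replicate = f"rep{(fov_index % cond.n_replicates) + 1}"
    stem = f"{cond.label}_{replicate}_fov{fov_index:03d}"
    fov = FieldOfView(
        channels,
        condition=cond.label,
        replicate=replicate,
        fov_id=f"{cond.label}/{stem}",
    )
    truth = pd.DataFrame(truth_rows)
    if not truth.empty:
        truth.insert(0, "condition", cond.label)
        truth.insert(1, "fov_id", fov.fov_id)
        truth.insert(2, "file", f"{stem}.tif")
        truth.insert(3, "replicate", replicate)
    return fov, truth


def generate_dataset(
    conditions: Sequence[ConditionSpec],
    out_root: Path | str,
    seed: int = 0,
) -> pd.DataFrame:
    """Write a condition-structured dataset plus ground truth to disk.

    Layout: ``out_root/<label>/<label>_repN_fovIII.tif`` readable by
    ``synmap.io.discover_dataset``/``read_field``; ``out_root/
    ground_truth.csv`` keyed by (condition, fov_id, cell); the generating
    parameters as ``generation.json``. Deterministic under a fixed seed.
    """
    out_root = Path(out_root)
    out_root.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    truths = []
    for cond in conditions:
        cond_dir = out_root / cond.label
        cond_dir.mkdir(exist_ok=True)
        for i in range(cond.n_fields):
            fov, truth = generate_field(cond, rng, i)
            stem = fov.fov_id.split("/", 1)[1]
            write_field(fov, cond_dir / f"{stem}.tif")
            if not truth.empty:
                truths.append(truth)
    gt = pd.concat(truths, ignore_index=True) if truths else pd.DataFrame()
    gt.to_csv(out_root / "ground_truth.csv", index=False, lineterminator="\n")
    gen_params = {
        "seed": seed,
        "conditions": [
            {
                "label": c.label,
                "n_fields": c.n_fields,
                "cells_per_field": c.cells_per_field,
                "field_shape": list(c.field_shape),
                "radius_range": list(c.radius_range),
                "f_c": c.f_c,
                "f_p": c.f_p,
                "background": c.background,
                "rho": c.rho,
                "rho_pair": list(c.rho_pair) if c.rho_pair else None,
                "n_replicates": c.n_replicates,
                "channels": [
                    {"name": ch.name, "weights": list(ch.weights), "fold": ch.fold, "noise_sd": ch.noise_sd}
                    for ch in c.channels
                ],
            }
            for c in conditions
        ],
    }
    (out_root / "generation.json").write_text(json.dumps(gen_params, indent=2) + "\n")
    return gt
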