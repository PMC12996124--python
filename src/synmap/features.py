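"""Per-cell morphology and intensity features, inclusion filters, and
bilayer-recruitment fold change.

Circularity is the compactness ratio 4*pi*A/P^2 (1 for a circle, pi/4 for a
square). Perimeters come from the chain-code weighted boundary estimator
(``skimage.measure.regionprops().perimeter``), pinned so circularity values
are reproducible across versions; rasterization can push the raw ratio
slightly above 1, so reported values are clamped at 1.0.

Recruitment fold change is the ratio of mean fluorescence inside the cell-
bilayer contact area to the mean of the free bilayer around it. It is
computed on RAW intensities: subtracting the background first would drive
the denominator toward zero and make the ratio meaningless. A guard band
around every mask keeps smoothed cell edges out of the denominator.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import regionprops

from .core import CellRecord, FieldOfView, LabelMask

logger = logging.getLogger(__name__)


def circularity(area_px: float, perimeter_px: float, clamp: bool = True) -> float:
    """Compactness 4*pi*A/P^2; 1.0 for an ideal circle, pi/4 for a square.

    ``clamp`` caps the value at 1.0 for reporting (rasterized near-circles
    can slightly exceed it).
    """
    if area_px < 1:
        raise ValueError(f"area must be >= 1 px, got {area_px}")
    if perimeter_px <= 0:
        raise ValueError(f"perimeter must be positive, got {perimeter_px}")
    val = 4.0 * math.pi * area_px / perimeter_px**2
    return min(val, 1.0) if clamp else val


def compute_features(field: FieldOfView, mask: LabelMask) -> list[CellRecord]:
    """One CellRecord per label: morphology plus per-channel MFI.

    MFI is the arithmetic mean of the channel's pixels under the label.
    Records are ordered by cell_id. An empty mask yields an empty list.
    """
    if mask.labels.shape != field.shape:
        raise ValueError(f"mask shape {mask.labels.shape} does not match field {field.shape}")
    px_um = field.channels[0].pixel_size_um
    records: list[CellRecord] = []
    props = {p.label: p for p in regionprops(mask.labels)}
    stacks = {ch.name: ch.pixels for ch in field.channels}
    for cell_id in sorted(props):
        p = props[cell_id]
        area = int(p.area)
        perim = float(p.perimeter)
        if perim <= 0:  # single-pixel or degenerate object
            perim = float(max(1, 2 * (p.bbox[2] - p.bbox[0]) + 2 * (p.bbox[3] - p.bbox[1])))
        under = mask.labels == cell_id
        mfi = {name: float(img[under].mean()) for name, img in stacks.items()}
        records.append(
            CellRecord(
                cell_id=int(cell_id),
                fov_id=field.fov_id,
                condition=field.condition,
                replicate=field.replicate,
                area_px=area,
                area_um2=area * px_um**2 if px_um is not None else None,
                perimeter_px=perim,
                circularity=circularity(area, perim),
                equiv_diameter_px=2.0 * math.sqrt(area / math.pi),
                centroid=(float(p.centroid[0]), float(p.centroid[1])),
                bbox=tuple(int(v) for v in p.bbox),
                mfi=mfi,
            )
        )
    return records


def inclusion_status(
    equiv_diameter_px: float,
    circ: float,
    diameter_range: tuple[float, float],
    circularity_range: tuple[float, float],
) -> tuple[bool, str]:
    """Inclusive-range morphology check; returns (included, reason string)."""
    d_lo, d_hi = diameter_range
    c_lo, c_hi = circularity_range
    if d_lo > d_hi or c_lo > c_hi:
        raise ValueError("filter range minima must not exceed maxima")
    reasons = []
    if not (d_lo <= equiv_diameter_px <= d_hi):
        reasons.append(f"diameter {equiv_diameter_px:.2f} outside [{d_lo:g}, {d_hi:g}]")
    if not (c_lo <= circ <= c_hi):
        reasons.append(f"circularity {circ:.3f} outside [{c_lo:g}, {c_hi:g}]")
    return (not reasons, "; ".join(reasons))


def filter_cells(
    records: Sequence[CellRecord],
    diameter_range: tuple[float, float],
    circularity_range: tuple[float, float],
) -> list[CellRecord]:
    """Annotate records with inclusion status; nothing is deleted.

    A cell is included when its equivalent-circle diameter and circularity
    both fall inside the (inclusive) ranges. Excluded records carry a reason
    string so downstream summaries can be re-derived when ranges change.
    Idempotent and order-independent.
    """
    out: list[CellRecord] = []
    for r in records:
        ok, why = inclusion_status(r.equiv_diameter_px, r.circularity, diameter_range, circularity_range)
        out.append(CellRecord(**{**r.__dict__, "included": ok, "exclusion_reason": why}))
    return out


def recruitment_fold_change(
    field: FieldOfView,
    mask: LabelMask,
    cell_id: Optional[int] = None,
    guard_band_px: int = 5,
) -> dict[int, dict[str, Optional[float]]]:
    """Per-channel MFI ratio of contact area to surrounding free bilayer.

    ``field`` must carry RAW (not background-subtracted) intensities. The
    denominator is the mean over pixels outside every label, after dilating
    all masks by ``guard_band_px`` so blur at cell edges does not leak in.
    A zero denominator reports the ratio as missing (None) with a warning.

    Returns {cell_id: {channel: fold or None}}; restricted to one cell when
    ``cell_id`` is given.
    """
    if mask.labels.shape != field.shape:
        raise ValueError("mask does not align with field")
    any_cell = mask.labels > 0
    if guard_band_px > 0 and any_cell.any():
        yy, xx = np.ogrid[-guard_band_px: guard_band_px + 1, -guard_band_px: guard_band_px + 1]
        disk = yy**2 + xx**2 <= guard_band_px**2
        outside = ~ndi.binary_dilation(any_cell, structure=disk)
    else:
        outside = ~any_cell
    ids = [cell_id] if cell_id is not None else mask.cell_ids
    result: dict[int, dict[str, Optional[float]]] = {i: {} for i in ids}
    for ch in field.channels:
        img = np.asarray(ch.pixels, dtype=float)
        if outside.any():
            denom = float(img[outside].mean())
        else:
            denom = 0.0
        if denom == 0.0:
            logger.warning(
                "field %s channel %s: outside-mask MFI is 0, fold change undefined",
                field.fov_id, ch.name,
            )
        for i in ids:
            under = mask.labels == i
            if not under.any():
                raise KeyError(f"cell {i} not present in mask")
            inside = float(img[under].mean())
            result[i][ch.name] = None if denom == 0.0 else inside / denom
    return result
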