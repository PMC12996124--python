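"""Core in-memory containers shared by all pipeline stages.

Conventions used throughout the package: images are 2D numpy arrays indexed
(row, col), 0-based, with pixel centers at integer coordinates. A field of
view is an ordered list of same-shaped channels. Label masks use 0 for
background and the contiguous label set {1..n} for cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

MIN_IMAGE_DIM = 8


@dataclass
class ChannelImage:
    """One fluorescence channel of a field of view.

    Parameters
    ----------
    pixels
        2D non-negative intensity grid, at least 8x8, all values finite.
    name
        Channel label (e.g. a ligand name); unique within a field.
    pixel_size_um
        Physical pixel size in micrometers per pixel, if known.
    """

    pixels: np.ndarray
    name: str
    pixel_size_um: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"channel {self.name!r}: pixels must be 2D, got ndim={self.pixels.ndim}")
        if min(self.pixels.shape) < MIN_IMAGE_DIM:
            raise ValueError(
                f"channel {self.name!r}: image must be at least "
                f"{MIN_IMAGE_DIM}x{MIN_IMAGE_DIM}, got {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError(f"channel {self.name!r}: non-finite intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class FieldOfView:
    """One multi-channel image with condition/replicate provenance."""

    channels: list[ChannelImage]
    condition: str = ""
    replicate: str = ""
    source_path: Optional[Path] = None
    fov_id: str = ""

    def __post_init__(self) -> None:
        if len(self.channels) == 0:
            raise ValueError("a field of view needs at least one channel")
        shapes = {c.shape for c in self.channels}
        if len(shapes) != 1:
            raise ValueError(f"channels differ in shape: {sorted(shapes)}")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError(f"channel names not unique: {names}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[0].shape

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def channel(self, name: str) -> ChannelImage:
        for c in self.channels:
            if c.name == name:
                return c
        raise KeyError(f"no channel named {name!r}; have {self.channel_names}")

    def as_stack(self) -> np.ndarray:
        """Channels stacked along axis 0, shape (C, H, W)."""
        return np.stack([c.pixels for c in self.channels])

    def with_channel_names(self, names: Sequence[str]) -> "FieldOfView":
        if len(names) != len(self.channels):
            raise ValueError(
                f"{len(names)} names for {len(self.channels)} channels in {self.fov_id or self.source_path}"
            )
        chans = [ChannelImage(c.pixels, n, c.pixel_size_um) for c, n in zip(self.channels, names)]
        return FieldOfView(chans, self.condition, self.replicate, self.source_path, self.fov_id)


@dataclass
class LabelMask:
    """Integer-labeled segmentation aligned to a field.

    0 is background; positive labels are exactly {1..n_cells} with no gaps,
    and each label forms one 4-connected component.
    """

    labels: np.ndarray
    seg_channel: str = ""
    backend_used: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label mask must be integer-typed")

    @property
    def n_cells(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def cell_ids(self) -> list[int]:
        return list(range(1, self.n_cells + 1))

    def validate(self) -> None:
        """Check the gap-free {1..n} labeling and 4-connectivity invariants."""
        from scipy import ndimage as ndi

        present = np.unique(self.labels)
        present = present[present > 0]
        expected = np.arange(1, self.n_cells + 1)
        if not np.array_equal(present, expected):
            raise ValueError(f"labels are not gap-free {{1..n}}: {present.tolist()}")
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        for lab in present:
            _, n_comp = ndi.label(self.labels == lab, structure=structure)
            if n_comp != 1:
                raise ValueError(f"label {lab} has {n_comp} 4-connected components")


@dataclass
class RadialProfile:
    """Mean intensity per integer radius bin 0..R from the synapse center."""

    values: np.ndarray
    counts: np.ndarray
    scaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.values.shape != self.counts.shape or self.values.ndim != 1:
            raise ValueError("values and counts must be equal-length 1D arrays")

    @property
    def length(self) -> int:
        return self.values.size


@dataclass
class RadialAverageImage:
    """Radially symmetric image within one cell's bounding box."""

    pixels: np.ndarray
    center: tuple[int, int]          # absolute (row, col) in the source image
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row_excl, max_col_excl)
    max_radius_px: int = 0


@dataclass
class ProfileEnsemble:
    """Per-bin mean and SEM over a stack of same-length radial profiles."""

    mean: np.ndarray
    sem: np.ndarray
    n_per_bin: np.ndarray
    n_cells: int
    normalized: bool = False


@dataclass
class CellRecord:
    """Morphology, intensity and colocalization features of one segmented synapse."""

    cell_id: int
    fov_id: str
    condition: str
    replicate: str
    area_px: int
    perimeter_px: float
    circularity: float
    equiv_diameter_px: float
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]
    area_um2: Optional[float] = None
    mfi: dict[str, float] = field(default_factory=dict)
    fold_change: dict[str, Optional[float]] = field(default_factory=dict)
    pcc: dict[tuple[str, str], Optional[float]] = field(default_factory=dict)
    included: bool = True
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.area_px < 1:
            raise ValueError("cell area must be >= 1 px")
        if self.circularity <= 0:
            raise ValueError("circularity must be positive")
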