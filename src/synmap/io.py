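"""Dataset discovery and TIFF / tabular I/O.

Input layout: a parent directory whose immediate subdirectories are
experimental conditions, each holding multi-plane TIFF files (one file per
field of view, channels as planes). Channel names and pixel size travel in a
small JSON document in the TIFF ImageDescription tag; files without it fall
back to "C0", "C1", ... Replicates are parsed from an optional ``repN``
token in the filename; otherwise each file is its own replicate.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .core import CellRecord, ChannelImage, FieldOfView

logger = logging.getLogger(__name__)

IMAGE_SUFFIXES = {".tif", ".tiff"}
_REP_RE = re.compile(r"rep(\d+)", re.IGNORECASE)


@dataclass(frozen=True)
class FieldDescriptor:
    """Pointer to one on-disk field of view, with its assigned condition."""

    path: Path
    condition: str
    replicate: str
    fov_id: str


def parse_replicate(filename: str) -> str:
    """Replicate token from a filename: 'repN' if present, else the stem."""
    m = _REP_RE.search(filename)
    if m:
        return f"rep{int(m.group(1))}"
    return Path(filename).stem


def discover_dataset(
    input_root: Path | str,
    overrides: Optional[dict[str, str]] = None,
) -> list[FieldDescriptor]:
    """Enumerate condition subfolders and their image files.

    Returns descriptors in deterministic order (lexicographic by subfolder
    then filename). Subfolder names become condition labels unless remapped
    via ``overrides``. Empty subfolders are reported but not fatal.
    """
    root = Path(input_root)
    if not root.is_dir():
        raise FileNotFoundError(f"input root does not exist or is not a directory: {root}")
    overrides = overrides or {}
    out: list[FieldDescriptor] = []
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        label = overrides.get(sub.name, sub.name)
        files = sorted(p for p in sub.iterdir() if p.is_file() and p.suffix.lower() in IMAGE_SUFFIXES)
        if not files:
            logger.warning("condition folder %s contains no image files", sub)
            continue
        for f in files:
            out.append(
                FieldDescriptor(
                    path=f,
                    condition=label,
                    replicate=parse_replicate(f.name),
                    fov_id=f"{sub.name}/{f.stem}",
                )
            )
    if not out:
        logger.warning("no image files found under %s", root)
    return out


# ---------------------------------------------------------------------------
# TIFF fields
# ---------------------------------------------------------------------------

def write_field(field: FieldOfView, path: Path | str) -> None:
    """Write a field as a multi-plane TIFF with channel names in the description tag."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"channel_names": field.channel_names}
    if field.channels[0].pixel_size_um is not None:
        meta["pixel_size_um"] = field.channels[0].pixel_size_um
    tifffile.imwrite(
        path,
        field.as_stack(),
        photometric="minisblack",
        description=json.dumps(meta),
        metadata=None,
    )


def _names_from_description(desc: Optional[str], n: int) -> tuple[list[str], Optional[float]]:
    if desc:
        try:
            meta = json.loads(desc)
            names = meta.get("channel_names")
            px = meta.get("pixel_size_um")
            if isinstance(names, list) and len(names) == n and all(isinstance(x, str) for x in names):
                return names, px
        except (json.JSONDecodeError, AttributeError):
            pass
    return [f"C{i}" for i in range(n)], None


def read_field(
    path: Path | str,
    expected_channels: Optional[int] = None,
    condition: str = "",
    replicate: Optional[str] = None,
    fov_id: Optional[str] = None,
) -> FieldOfView:
    """Read a multi-plane TIFF into a FieldOfView, channels ordered as stored.

    Integer intensities are preserved losslessly. A channel-count mismatch
    against ``expected_channels`` is fatal and names the file.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description if tf.pages else None
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected 2D planes, got array of shape {arr.shape}")
    n = arr.shape[0]
    if expected_channels is not None and n != expected_channels:
        raise ValueError(f"{path}: has {n} channels, expected {expected_channels}")
    names, px = _names_from_description(desc, n)
    channels = [ChannelImage(arr[i], names[i], px) for i in range(n)]
    return FieldOfView(
        channels=channels,
        condition=condition,
        replicate=replicate if replicate is not None else parse_replicate(path.name),
        source_path=path,
        fov_id=fov_id if fov_id is not None else path.stem,
    )


def read_descriptor(desc: FieldDescriptor, expected_channels: Optional[int] = None) -> FieldOfView:
    return read_field(
        desc.path,
        expected_channels=expected_channels,
        condition=desc.condition,
        replicate=desc.replicate,
        fov_id=desc.fov_id,
    )


# ---------------------------------------------------------------------------
# Per-cell tables
# ---------------------------------------------------------------------------

def _pair_col(pair: tuple[str, str]) -> str:
    a, b = sorted(pair)
    return f"pcc_{a}__{b}"


def cell_table_columns(channel_names: Sequence[str], pairs: Sequence[tuple[str, str]]) -> list[str]:
    """Fixed column order of the per-cell CSV."""
    cols = [
        "fov_id", "cell_id", "condition", "replicate",
        "area_px", "area_um2", "perimeter_px", "circularity", "equiv_diameter_px",
        "centroid_row", "centroid_col",
        "bbox_min_row", "bbox_min_col", "bbox_max_row", "bbox_max_col",
    ]
    cols += [f"mfi_{c}" for c in channel_names]
    cols += [f"fold_{c}" for c in channel_names]
    cols += [_pair_col(p) for p in pairs]
    cols += ["included", "exclusion_reason"]
    return cols


def records_to_frame(
    records: Iterable[CellRecord],
    channel_names: Sequence[str],
    pairs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Flatten CellRecords to a DataFrame with the fixed column order.

    All segmented cells appear, excluded ones flagged ``included=False``
    rather than dropped.
    """
    rows = []
    for r in records:
        row: dict = {
            "fov_id": r.fov_id,
            "cell_id": r.cell_id,
            "condition": r.condition,
            "replicate": r.replicate,
            "area_px": r.area_px,
            "area_um2": r.area_um2 if r.area_um2 is not None else np.nan,
            "perimeter_px": r.perimeter_px,
            "circularity": r.circularity,
            "equiv_diameter_px": r.equiv_diameter_px,
            "centroid_row": r.centroid[0],
            "centroid_col": r.centroid[1],
            "bbox_min_row": r.bbox[0],
            "bbox_min_col": r.bbox[1],
            "bbox_max_row": r.bbox[2],
            "bbox_max_col": r.bbox[3],
            "included": r.included,
            "exclusion_reason": r.exclusion_reason,
        }
        for c in channel_names:
            row[f"mfi_{c}"] = r.mfi.get(c, np.nan)
        for c in channel_names:
            fc = r.fold_change.get(c)
            row[f"fold_{c}"] = np.nan if fc is None else fc
        for p in pairs:
            v = r.pcc.get(tuple(sorted(p)))
            row[_pair_col(p)] = np.nan if v is None else v
        rows.append(row)
    cols = cell_table_columns(channel_names, pairs)
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)[cols]


def write_cell_table(
    records: Iterable[CellRecord],
    path: Path | str,
    channel_names: Sequence[str],
    pairs: Sequence[tuple[str, str]] = (),
) -> None:
    """Write the per-cell CSV (header-only when there are no records)."""
    df = records_to_frame(records, channel_names, pairs)
    write_table(df, path)


def write_table(df: pd.DataFrame, path: Path | str) -> None:
    """CSV writer used for every tabular output.

    Floats use the shortest round-trip repr: deterministic, lossless, and
    byte-stable across reruns, which the refilter contract relies on.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n")


def read_table(path: Path | str) -> pd.DataFrame:
    """Read back a pipeline CSV with exact (round-trip) float parsing.

    The default pandas float parser can be off by 1 ulp, which would break
    the byte-identical refilter contract; the round_trip parser restores the
    exact doubles that were written.
    """
    return pd.read_csv(path, float_precision="round_trip")
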