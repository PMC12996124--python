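"""Pixel-wise Pearson colocalization within segmented synapses.

The Pearson product-moment coefficient of the paired pixel intensities of
two channels, restricted to one cell's mask, ranges from -1 (mutually
exclusive localization) through 0 (no linear relationship) to +1 (complete
colocalization). It is invariant to positive-slope affine transforms of
either channel, so acquisition gain and offset do not affect it.

By default the coefficient is computed on background-subtracted intensities
over mask pixels only — colocalization across the synaptic interface is the
quantity of interest, not the surrounding bilayer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import CellRecord, ChannelImage, LabelMask


@dataclass
class PCCResult:
    """Pearson coefficient for one cell and one (alphabetical) channel pair."""

    cell_id: int
    channel_pair: tuple[str, str]
    coefficient: Optional[float]
    n_pixels: int
    reason: str = ""

    def __post_init__(self) -> None:
        self.channel_pair = tuple(sorted(self.channel_pair))  # type: ignore[assignment]
        if self.coefficient is not None and not -1.0 <= self.coefficient <= 1.0:
            raise ValueError(f"coefficient {self.coefficient} outside [-1, 1]")


def pearson_cc(
    a: ChannelImage,
    b: ChannelImage,
    mask: LabelMask,
    cell_id: int,
) -> PCCResult:
    """Pearson coefficient of two channels over one cell's mask pixels.

    Degenerate inputs are reported as missing rather than fatal: fewer than
    two pixels, or a channel with zero variance under the mask ("constant
    channel").
    """
    under = mask.labels == cell_id
    n = int(under.sum())
    pair = tuple(sorted((a.name, b.name)))
    if n < 2:
        return PCCResult(cell_id, pair, None, n, reason="fewer than 2 pixels")
    x = np.asarray(a.pixels, dtype=float)[under]
    y = np.asarray(b.pixels, dtype=float)[under]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return PCCResult(cell_id, pair, None, n, reason="constant channel")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        return PCCResult(cell_id, pair, None, n, reason="constant channel")
    r = float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))
    return PCCResult(cell_id, pair, r, n)


def shuffle_null(
    a: ChannelImage,
    b: ChannelImage,
    mask: LabelMask,
    cell_id: int,
    rng: np.random.Generator,
    n_shuffles: int = 100,
) -> np.ndarray:
    """Pixel-shuffle null distribution of the per-cell coefficient.

    Optional diagnostic: permuting one channel's pixels under the mask
    destroys spatial correspondence, so the spread of the resulting
    coefficients indicates the magnitude expected by chance alone.
    """
    under = mask.labels == cell_id
    x = np.asarray(a.pixels, dtype=float)[under]
    y = np.asarray(b.pixels, dtype=float)[under].copy()
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.array([])
    out = np.empty(n_shuffles)
    for i in range(n_shuffles):
        rng.shuffle(y)
        out[i] = np.corrcoef(x, y)[0, 1]
    return out


def aggregate_pcc(
    results: Sequence[PCCResult],
    records: Sequence[CellRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Condition-level colocalization summary over included cells.

    Returns ``(summary, replicate_medians)``: the summary holds, per
    condition x channel pair, the cell count, overall median and IQR
    (Q3 - Q1) of per-cell coefficients; the second table holds the median
    per biological replicate, the unit used for inference in practice.
    Only cells whose record passed the inclusion filters contribute.
    """
    # per-cell coefficients live on the records (the pipeline copies them
    # there from pearson_cc); bare results are matched by cell_id for
    # records that were not annotated, which is only unambiguous when each
    # cell_id occurs once.
    by_cell: dict[int, dict[tuple[str, str], Optional[float]]] = {}
    cell_id_counts: dict[int, int] = {}
    for r in records:
        cell_id_counts[r.cell_id] = cell_id_counts.get(r.cell_id, 0) + 1
    for res in results:
        if cell_id_counts.get(res.cell_id, 0) == 1:
            by_cell.setdefault(res.cell_id, {})[res.channel_pair] = res.coefficient
    flat = []
    for r in records:
        if not r.included:
            continue
        pcc_map = r.pcc if r.pcc else by_cell.get(r.cell_id, {})
        for pair, val in sorted(pcc_map.items()):
            if val is None:
                continue
            flat.append(
                {
                    "condition": r.condition,
                    "replicate": r.replicate,
                    "pair": f"{pair[0]}__{pair[1]}",
                    "fov_id": r.fov_id,
                    "cell_id": r.cell_id,
                    "pcc": val,
                }
            )
    if not flat:
        cols_s = ["condition", "pair", "n_cells", "median", "q1", "q3", "iqr", "n_replicates"]
        cols_r = ["condition", "pair", "replicate", "median", "n_cells"]
        return pd.DataFrame(columns=cols_s), pd.DataFrame(columns=cols_r)
    df = pd.DataFrame(flat)
    rep = (
        df.groupby(["condition", "pair", "replicate"], sort=True)["pcc"]
        .agg(median="median", n_cells="count")
        .reset_index()
    )
    summary = (
        df.groupby(["condition", "pair"], sort=True)["pcc"]
        .agg(
            n_cells="count",
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
        )
        .reset_index()
    )
    summary["iqr"] = summary["q3"] - summary["q1"]
    n_reps = (
        rep.groupby(["condition", "pair"])["replicate"].nunique().rename("n_replicates").reset_index()
    )
    summary = summary.merge(n_reps, on=["condition", "pair"], how="left")
    return summary, rep
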