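"""Batch orchestration: run the full analysis, refilter, and report.

``run_pipeline`` executes discover -> read -> background subtraction ->
segmentation -> feature extraction -> filtering -> radial averaging ->
colocalization -> aggregation, and writes every tabular/image output plus a
run manifest. All non-timestamp output bytes are a pure function of
(dataset, config): rerunning with the same config reproduces them exactly.

``refilter`` re-derives inclusion flags and every downstream aggregate from
the stored per-cell data without re-segmentation, so tightening or widening
the morphology sliders is cheap and exactly equivalent to a fresh run with
the same ranges.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig, read_config, write_config
from .coloc import pearson_cc
from .core import CellRecord, FieldOfView, LabelMask, RadialAverageImage, RadialProfile
from .features import compute_features, filter_cells, inclusion_status, recruitment_fold_change
from .io import (
    discover_dataset,
    read_descriptor,
    read_table,
    records_to_frame,
    write_table,
)
from .radial import aggregate_profiles, build_group_outputs, radial_average, scale_profile
from .segment import segment, subtract_background

logger = logging.getLogger(__name__)

CELLS_ALL = "cells_all.csv"
PROFILES_PER_CELL = "profiles_per_cell.csv"


@dataclass
class RunResult:
    """In-memory handle on a completed (or refiltered) run."""

    output_dir: Path
    cell_table: pd.DataFrame
    pcc_summary: pd.DataFrame
    pcc_replicates: pd.DataFrame
    mfi_summary: pd.DataFrame
    fold_summary: pd.DataFrame
    manifest: dict


def _subtract_unclipped(field: FieldOfView, backgrounds: dict[str, float]) -> FieldOfView:
    """Shift each channel by its background estimate without clipping at 0."""
    from .core import ChannelImage

    channels = [
        ChannelImage(ch.pixels.astype(float) - backgrounds[ch.name], ch.name, ch.pixel_size_um)
        for ch in field.channels
    ]
    return FieldOfView(channels, field.condition, field.replicate, field.source_path, field.fov_id)


def _channel_pairs(names: Sequence[str]) -> list[tuple[str, str]]:
    out = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            out.append(tuple(sorted((a, b))))
    return sorted(out)


def run_pipeline(config: AnalysisConfig, make_plots: bool = True) -> RunResult:
    """Execute the full batch analysis described by ``config``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    descriptors = discover_dataset(config.input_root, config.condition_labels)

    all_records: list[CellRecord] = []
    profile_rows: list[dict] = []
    radial_images: dict[tuple[str, str], list[tuple[str, int, RadialAverageImage]]] = {}
    backgrounds: dict[str, dict[str, float]] = {}
    channel_names: Optional[list[str]] = list(config.channel_names) if config.channel_names else None

    for desc in descriptors:
        field = read_descriptor(desc)
        if config.channel_names:
            field = field.with_channel_names(config.channel_names)
        if channel_names is None:
            channel_names = field.channel_names
        if field.channel_names != channel_names:
            raise RuntimeError(
                f"{desc.path}: channel names {field.channel_names} differ from {channel_names}"
            )
        # first pass is mask-free (lowest-quartile median); once a mask
        # exists the estimate is refined to the median outside all cells
        field0, _ = subtract_background(field)
        mask = segment(field0, config)
        sub, bgs = subtract_background(field, mask)
        backgrounds[desc.fov_id] = bgs
        records = compute_features(sub, mask)
        folds = recruitment_fold_change(field, mask, guard_band_px=config.guard_band_px)
        # PCC uses unclipped subtraction: Pearson is invariant to the scalar
        # shift, while clipping at 0 would censor sub-background pixels and
        # attenuate the coefficient
        pcc_source = field if config.pcc_on_raw else _subtract_unclipped(field, backgrounds[desc.fov_id])
        pairs = _channel_pairs(channel_names)
        for rec in records:
            rec.fold_change = folds[rec.cell_id]
            for a, b in pairs:
                res = pearson_cc(pcc_source.channel(a), pcc_source.channel(b), mask, rec.cell_id)
                rec.pcc[res.channel_pair] = res.coefficient
        for rec in records:
            for ch in sub.channels:
                img, prof = radial_average(ch.pixels, mask, rec.cell_id, mask_only=config.radial_mask_only)
                if config.scale_profiles and prof.length >= 2:
                    prof = scale_profile(prof, config.radial_target_length)
                radial_images.setdefault((desc.condition, ch.name), []).append(
                    (desc.fov_id, rec.cell_id, img)
                )
                for b, v in enumerate(prof.values):
                    profile_rows.append(
                        {
                            "condition": desc.condition,
                            "fov_id": desc.fov_id,
                            "cell_id": rec.cell_id,
                            "channel": ch.name,
                            "bin": b,
                            "value": v,
                        }
                    )
        all_records.extend(records)

    if channel_names is None:
        channel_names = []
    pairs = _channel_pairs(channel_names)
    all_records = filter_cells(all_records, config.diameter_filter, config.circularity_filter)
    cell_df = records_to_frame(all_records, channel_names, pairs)
    write_table(cell_df, out / CELLS_ALL)
    prof_df = pd.DataFrame(
        profile_rows, columns=["condition", "fov_id", "cell_id", "channel", "bin", "value"]
    )
    write_table(prof_df, out / PROFILES_PER_CELL)

    summaries = _write_aggregates(out, cell_df, prof_df, channel_names, config)

    # radial TIFF triplets per condition x channel, included cells only
    included_keys = set(
        zip(cell_df.loc[cell_df["included"], "fov_id"], cell_df.loc[cell_df["included"], "cell_id"])
    )
    for (condition, channel), entries in sorted(radial_images.items()):
        imgs = [im for fov, cid, im in entries if (fov, cid) in included_keys]
        build_group_outputs(imgs, channel, out / condition)

    manifest = {
        "software": {"name": "synmap", "version": __version__},
        "config": config.model_dump(mode="json"),
        "seed": config.rng_seed,
        "background_estimates": backgrounds,
        "cell_counts": _condition_counts(cell_df),
        "n_fields": len(descriptors),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    write_config(config, out / "config.json")

    if make_plots:
        from . import plots
        plots.write_all(out, cell_df, channel_names, config)

    return RunResult(out, cell_df, *summaries, manifest)


def _condition_counts(cell_df: pd.DataFrame) -> dict:
    counts: dict = {}
    if cell_df.empty:
        return counts
    for cond, grp in cell_df.groupby("condition", sort=True):
        counts[cond] = {"segmented": int(len(grp)), "included": int(grp["included"].sum())}
    return counts


def _write_aggregates(
    out: Path,
    cell_df: pd.DataFrame,
    prof_df: pd.DataFrame,
    channel_names: Sequence[str],
    config: AnalysisConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Write all aggregate tables from per-cell data (shared by run and refilter)."""
    inc = cell_df[cell_df["included"]] if not cell_df.empty else cell_df

    # per-condition per-cell tables (all cells, with flags)
    if not cell_df.empty:
        for cond, grp in cell_df.groupby("condition", sort=True):
            write_table(grp.reset_index(drop=True), out / str(cond) / "cells.csv")

    # intensity profiles: mean +/- SEM per condition x channel over included cells
    if not prof_df.empty and not inc.empty:
        key = set(zip(inc["fov_id"], inc["cell_id"]))
        sel = prof_df[[ (f, c) in key for f, c in zip(prof_df["fov_id"], prof_df["cell_id"]) ]]
        for (cond, channel), grp in sel.groupby(["condition", "channel"], sort=True):
            profiles = [
                RadialProfile(
                    values=sub.sort_values("bin")["value"].to_numpy(),
                    counts=np.ones(len(sub)),
                    scaled=config.scale_profiles,
                )
                for _, sub in grp.groupby(["fov_id", "cell_id"], sort=True)
            ]
            ens = aggregate_profiles(profiles, normalize=config.normalize_profiles)
            table = pd.DataFrame(
                {
                    "bin": np.arange(ens.mean.size),
                    "mean": ens.mean,
                    "sem": ens.sem,
                    "n": ens.n_per_bin,
                }
            )
            write_table(table, out / str(cond) / f"profile_{channel}.csv")

    # MFI and fold-change summaries per condition x channel
    mfi_rows, fold_rows = [], []
    if not inc.empty:
        ref_medians: dict[tuple[str, str], float] = {}
        if config.reference_condition is not None:
            ref = inc[inc["condition"] == config.reference_condition]
            for ch in channel_names:
                for rep, grp in ref.groupby("replicate", sort=True):
                    ref_medians[(ch, rep)] = float(grp[f"fold_{ch}"].median())
        for cond in sorted(inc["condition"].unique()):
            grp = inc[inc["condition"] == cond]
            for ch in channel_names:
                mfi = grp[f"mfi_{ch}"].dropna()
                mfi_rows.append(
                    {
                        "condition": cond, "channel": ch, "n_cells": int(mfi.size),
                        "median": mfi.median(), "q1": mfi.quantile(0.25), "q3": mfi.quantile(0.75),
                    }
                )
                fold = grp[f"fold_{ch}"].dropna()
                row = {
                    "condition": cond, "channel": ch, "n_cells": int(fold.size),
                    "median": fold.median(), "q1": fold.quantile(0.25), "q3": fold.quantile(0.75),
                }
                if config.reference_condition is not None:
                    rescaled = [
                        v / ref_medians[(ch, rep)]
                        for v, rep in zip(grp[f"fold_{ch}"], grp["replicate"])
                        if pd.notna(v) and ref_medians.get((ch, rep), 0) not in (0, None)
                    ]
                    row["median_rescaled"] = float(np.median(rescaled)) if rescaled else np.nan
                fold_rows.append(row)
    mfi_summary = pd.DataFrame(mfi_rows, columns=["condition", "channel", "n_cells", "median", "q1", "q3"])
    fold_cols = ["condition", "channel", "n_cells", "median", "q1", "q3"]
    if config.reference_condition is not None:
        fold_cols.append("median_rescaled")
    fold_summary = pd.DataFrame(fold_rows, columns=fold_cols)
    write_table(mfi_summary, out / "mfi_summary.csv")
    write_table(fold_summary, out / "fold_summary.csv")

    pcc_summary, pcc_rep = _pcc_tables(inc)
    write_table(pcc_summary, out / "pcc_summary.csv")
    write_table(pcc_rep, out / "pcc_replicate_medians.csv")
    return pcc_summary, pcc_rep, mfi_summary, fold_summary


def _pcc_tables(inc: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Condition x channel-pair PCC summary from the included per-cell rows."""
    cols_s = ["condition", "pair", "n_cells", "median", "q1", "q3", "iqr", "n_replicates"]
    cols_r = ["condition", "pair", "replicate", "median", "n_cells"]
    pcc_cols = [c for c in inc.columns if c.startswith("pcc_")] if not inc.empty else []
    rows = []
    for c in pcc_cols:
        pair = c[len("pcc_"):]
        sub = inc[["condition", "replicate", c]].dropna(subset=[c])
        for _, r in sub.iterrows():
            rows.append(
                {"condition": r["condition"], "replicate": r["replicate"], "pair": pair, "pcc": r[c]}
            )
    if not rows:
        return pd.DataFrame(columns=cols_s), pd.DataFrame(columns=cols_r)
    df = pd.DataFrame(rows)
    rep = (
        df.groupby(["condition", "pair", "replicate"], sort=True)["pcc"]
        .agg(median="median", n_cells="count")
        .reset_index()
    )
    summary = (
        df.groupby(["condition", "pair"], sort=True)["pcc"]
        .agg(n_cells="count", median="median", q1=lambda s: s.quantile(0.25), q3=lambda s: s.quantile(0.75))
        .reset_index()
    )
    summary["iqr"] = summary["q3"] - summary["q1"]
    n_reps = rep.groupby(["condition", "pair"])["replicate"].nunique().rename("n_replicates").reset_index()
    summary = summary.merge(n_reps, on=["condition", "pair"], how="left")
    return summary[cols_s], rep[cols_r]


def refilter(
    output_dir: Path | str,
    diameter_range: tuple[float, float],
    circularity_range: tuple[float, float],
    make_plots: bool = True,
) -> RunResult:
    """Recompute inclusion flags and all aggregate tables from stored per-cell data.

    Requires a prior ``run_pipeline`` output tree (the all-cells table and
    per-cell profile store). No re-segmentation happens; the result is
    exactly equivalent to a fresh run with the new ranges on every aggregate
    table.
    """
    out = Path(output_dir)
    cells_path = out / CELLS_ALL
    prof_path = out / PROFILES_PER_CELL
    if not cells_path.exists() or not prof_path.exists():
        raise FileNotFoundError(
            f"refilter needs {CELLS_ALL} and {PROFILES_PER_CELL} under {out}; run the pipeline first"
        )
    config = read_config(out / "config.json")
    config = config.model_copy(
        update={"diameter_filter": tuple(diameter_range), "circularity_filter": tuple(circularity_range)}
    )
    cell_df = read_table(cells_path)
    prof_df = read_table(prof_path)
    if not cell_df.empty:
        included, reasons = [], []
        for d, c in zip(cell_df["equiv_diameter_px"], cell_df["circularity"]):
            ok, why = inclusion_status(d, c, tuple(diameter_range), tuple(circularity_range))
            included.append(ok)
            reasons.append(why)
        cell_df["included"] = included
        cell_df["exclusion_reason"] = reasons
    write_table(cell_df, cells_path)
    channel_names = [c[len("mfi_"):] for c in cell_df.columns if c.startswith("mfi_")]
    summaries = _write_aggregates(out, cell_df, prof_df, channel_names, config)
    write_config(config, out / "config.json")
    manifest_path = out / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    manifest["config"] = config.model_dump(mode="json")
    manifest["cell_counts"] = _condition_counts(cell_df)
    manifest["timestamp"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    if make_plots:
        from . import plots
        plots.write_all(out, cell_df, channel_names, config)
    return RunResult(out, cell_df, *summaries, manifest)
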