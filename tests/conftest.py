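"""Shared fixtures: small synthetic datasets and run configurations.

All fixtures are generated programmatically at test time; nothing is read
from checked-in binary data.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

import synmap as sm
from synmap.synthetic import ConditionSpec, default_channels, generate_dataset


def small_conditions(rhos=(0.0, 0.6), n_fields=2, cells_per_field=3) -> list[ConditionSpec]:
    """Miniature study conditions: small cells and fields for fast tests."""
    return [
        ConditionSpec(
            label=f"rho{int(round(r * 10)):02d}",
            n_fields=n_fields,
            cells_per_field=cells_per_field,
            channels=default_channels(),
            rho=r,
            rho_pair=("ligA", "ligB"),
            field_shape=(160, 160),
            radius_range=(12.0, 16.0),
        )
        for r in rhos
    ]


def small_config(input_root: Path, output_dir: Path, **overrides) -> sm.AnalysisConfig:
    kwargs = dict(
        input_root=input_root,
        output_dir=output_dir,
        segmentation_channel="actin",
        diameter_px=28.0,
    )
    kwargs.update(overrides)
    return sm.AnalysisConfig(**kwargs)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory) -> tuple[Path, "object"]:
    """A 2-condition on-disk dataset with ground truth (session-cached)."""
    root = tmp_path_factory.mktemp("tiny_data")
    gt = generate_dataset(small_conditions(), root, seed=11)
    return root, gt


@pytest.fixture(scope="session")
def tiny_run(tiny_dataset, tmp_path_factory):
    """One completed pipeline run on the tiny dataset (session-cached)."""
    root, gt = tiny_dataset
    out = tmp_path_factory.mktemp("tiny_out")
    config = small_config(root, out)
    result = sm.run_pipeline(config, make_plots=False)
    return config, result, gt


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def disk_mask(shape: tuple[int, int], center: tuple[int, int], radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0: shape[0], 0: shape[1]]
    return np.hypot(rr - center[0], cc - center[1]) <= radius
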