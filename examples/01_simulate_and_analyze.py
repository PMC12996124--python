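"""Simulate a two-condition synapse experiment and run the full pipeline.

Generates synthetic TIRF-like fields in which the flat ligand pair
(ligA/ligB) is uncorrelated in one condition and correlated at rho = 0.6 in
the other, then runs segmentation -> features -> filtering -> radial
averaging -> colocalization and prints the condition-level summaries.
"""

import tempfile
from pathlib import Path

import synmap as sm
from synmap.synthetic import ConditionSpec, default_channels

tmp = Path(tempfile.mkdtemp(prefix="synmap_demo_"))
conditions = [
    ConditionSpec("uncorrelated", n_fields=3, cells_per_field=4,
                  channels=default_channels(), rho=0.0, rho_pair=("ligA", "ligB")),
    ConditionSpec("corr06", n_fields=3, cells_per_field=4,
                  channels=default_channels(), rho=0.6, rho_pair=("ligA", "ligB")),
]
gt = sm.generate_dataset(conditions, tmp / "data", seed=1)
print(f"generated {len(gt)} synapses in {tmp/'data'}")

config = sm.AnalysisConfig(
    input_root=tmp / "data",
    output_dir=tmp / "out",
    segmentation_channel="actin",   # whole-contact channel drives segmentation
    diameter_px=100.0,              # expected synapse diameter in pixels
    diameter_filter=(60.0, 130.0),  # equivalent-circle diameter slider, px
    circularity_filter=(0.7, 1.0),
)
result = sm.run_pipeline(config)

print("\ncells per condition (segmented / included):")
for cond, c in result.manifest["cell_counts"].items():
    print(f"  {cond}: {c['segmented']} / {c['included']}")

print("\nligand-pair colocalization (median per-cell PCC — should track rho):")
lig = result.pcc_summary.query("pair == 'ligA__ligB'")
print(lig[["condition", "n_cells", "median", "iqr"]].to_string(index=False))

print("\nrecruitment fold change (contact MFI / free-bilayer MFI; tcr and cd2"
      "\nare enriched 3x by construction, ligands are not enriched):")
print(result.fold_summary[["condition", "channel", "median"]].to_string(index=False))
print(f"\nfull output tree (tables, radial TIFFs, plots): {tmp/'out'}")
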