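# synmap

Quantitative mapping of the immunological synapse (IS) from multi-channel
fluorescence micrographs.

When a T cell engages a supported lipid bilayer (SLB) presenting mobile,
fluorescently tagged ligands, the contact interface organizes into
concentric domains — the central cSMAC (TCR), the pSMAC ring (LFA-1/ICAM-1)
and the distal dSMAC, where receptors such as CD2 can form a "corolla" of
petals. TIRF microscopy images exactly this interface plane, one 2D
multi-channel field of view at a time. `synmap` turns folders of such fields
(one subfolder per experimental condition) into per-cell and per-condition
quantities:

- **Segmentation** of individual synapses, with a deterministic built-in
  segmenter (Gaussian–Otsu–watershed, parameterized only by the expected
  diameter) and an adapter seam for external deep-learning backends. Images
  are shrunk by a pre-inference scale *s* ∈ [0.3, 1], the target diameter is
  scaled with them, and masks are mapped back to full resolution.
- **Morphology filtering** by equivalent-circle diameter
  d = 2√(A/π) and circularity 4πA/P² (1 for a circle, π/4 for a square);
  excluded cells are flagged, never dropped, so filters can be re-applied
  instantly (`refilter`) without re-segmentation.
- **Per-cell features**: area, perimeter, circularity, per-channel mean
  fluorescence intensity (MFI), and **recruitment fold change** — the ratio
  of MFI inside the cell–bilayer contact to the MFI of the surrounding free
  bilayer (computed on raw intensities, with a guard band around every cell).
- **Radial averaging**: each pixel in a cell's bounding box is replaced by
  the mean intensity of all pixels at the same integer radius from the
  synapse center, giving a rotationally symmetric image and a radius-vs-MFI
  profile; profiles can be rescaled to a common length and aggregated per
  condition as mean ± SEM. Per condition and channel the package writes
  `<Channel>_radMontage.tif`, `<Channel>_radStack.tif` and
  `<Channel>_radTotAv.tif`.
- **Colocalization**: the Pearson correlation coefficient (PCC) of paired
  pixel intensities for every channel pair within each synapse mask
  (+1 colocalized, 0 unrelated, −1 mutually exclusive), summarized as
  per-cell values, per-replicate medians and condition median ± IQR.
- **A synthetic-synapse generator** that renders datasets
  with exact ground truth (geometry, enrichment folds, inter-channel
  correlations), written in the same condition-folder layout, so every stage
  of the pipeline is testable without microscope data.

Every run writes a JSON config and manifest sufficient to reproduce it;
rerunning with the same config reproduces every table byte-for-byte.

## Worked example

`examples/01_simulate_and_analyze.py` simulates two conditions in which a
pair of flat bilayer ligands is uncorrelated vs correlated at ρ = 0.6, then
runs the full pipeline:

```
ligand-pair colocalization (median per-cell PCC — should track rho):
   condition  n_cells    median      iqr
      corr06       12  0.603624 0.010502
uncorrelated       12 -0.007292 0.017370

recruitment fold change (contact MFI / free-bilayer MFI; ...):
   condition channel   median
      corr06   actin 2.989677
      corr06     tcr 2.975844
      corr06     cd2 3.004162
      corr06    ligA 1.000449
```

The PCC medians recover the generating correlations (0.60 and ≈0), and the
fold changes recover the constructed 3× enrichment of the cell channels
while the non-enriched ligands sit at 1.0. `examples/02_radial_averaging.py`
shows the radial profiles peaking at radius 0 for a central-domain channel
and at ≈0.9× the cell radius for a distal-ring channel;
`examples/03_colocalization.py` contrasts a measured PCC with its
pixel-shuffle null.

Equivalent shell usage:

```sh
synmap generate demo_data --labels a,b --rhos 0.0,0.6 --seed 1
synmap run config.json            # config.json points input_root at demo_data
synmap refilter out --diameter-min 60 --diameter-max 130
```

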