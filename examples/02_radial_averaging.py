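"""Radially average one synthetic synapse and locate each channel's peak.

The ring-replacement operator substitutes every pixel with the mean of all
pixels at the same integer radius from the synapse center, turning each cell
into a rotationally symmetric image plus a 1D radius-vs-intensity profile.
A central (cSMAC-like) channel peaks at radius 0; a distal-ring (corolla-
like) channel peaks near 0.9x the cell radius, mid-way through its annulus.
"""

import numpy as np

import synmap as sm
from synmap.core import LabelMask
from synmap.synthetic import ChannelModel, SynapseSpec

spec = SynapseSpec(
    radius_px=45.0,
    channels=[
        ChannelModel("tcr", weights=(1, 0, 0), fold=3.0, noise_sd=8.0),   # central disk
        ChannelModel("icam", weights=(0, 1, 0), fold=3.0, noise_sd=8.0),  # intermediate ring
        ChannelModel("cd2", weights=(0, 0, 1), fold=3.0, noise_sd=8.0),   # distal corolla
    ],
)
tile, mask, truth = sm.render_synapse(spec, rng_seed=0)
label_mask = LabelMask(mask.astype(np.int32))

print(f"synapse radius {spec.radius_px} px, domains split at "
      f"{spec.f_c:.0%} and {spec.f_p:.0%} of the radius\n")
for i, ch in enumerate(spec.channels):
    rad_img, profile = sm.radial_average(tile[i], label_mask, 1)
    scaled = sm.scale_profile(profile, target_length=100)
    peak = int(np.nanargmax(profile.values))
    expected = truth["channels"][ch.name]["peak_radius_px"]
    print(f"{ch.name:>5}: profile peak at radius {peak:2d} px "
          f"(noise-free construction predicts {expected} px); "
          f"scaled peak bin {int(np.nanargmax(scaled.values))}/100")

print("\nEach profile value is the mean intensity of one integer-radius ring;"
      "\nscaling resamples profiles to a common length so cells of different"
      "\nsizes can be averaged bin-by-bin.")
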