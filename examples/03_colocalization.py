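"""Pearson colocalization inside the synapse mask, with a known answer.

Builds two channels that share Gaussian noise at a chosen correlation rho
within one synthetic synapse and shows that the per-cell Pearson coefficient
over mask pixels recovers rho, while a pixel-shuffle null centers on zero.
"""

import numpy as np

import synmap as sm
from synmap.core import ChannelImage, LabelMask
from synmap.synthetic import correlated_pair

rng = np.random.default_rng(0)
rho = 0.7
shape = (128, 128)

# a synapse mask plus two ligand channels: flat signal + correlated noise
rr, cc = np.mgrid[0: shape[0], 0: shape[1]]
mask = LabelMask((np.hypot(rr - 64, cc - 64) <= 45).astype(np.int32))
za, zb = correlated_pair(shape, rho, rng)
a = ChannelImage(200.0 + 10.0 * za, "ligA")
b = ChannelImage(200.0 + 10.0 * zb, "ligB")

res = sm.pearson_cc(a, b, mask, cell_id=1)
print(f"generating correlation rho = {rho}")
print(f"measured PCC over {res.n_pixels} mask pixels = {res.coefficient:.3f}")

from synmap.coloc import shuffle_null

null = shuffle_null(a, b, mask, 1, rng, n_shuffles=200)
print(f"pixel-shuffle null: mean {null.mean():+.4f}, sd {null.std():.4f}")
print("\nThe measured coefficient sits at the generating rho (sampling error"
      f"\n~(1-rho^2)/sqrt(n) = {(1-rho**2)/np.sqrt(res.n_pixels):.3f}), while shuffling destroys the spatial"
      "\ncorrespondence and collapses the coefficient to ~0.")
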