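"""Weighted distance bins versus midpoint bins on an ordered lattice.

Dummy atoms cut from a density map sit on a regular grid, so their pair
distances cluster on a few exact values.  Snapping those distances to bin
midpoints biases the Debye sum; storing each bin's weight-weighted centre of
mass removes the bias at no extra cost.  This script quantifies both against
the exact (unbinned) Debye double sum on an 8x8x8 lattice of 2 A spacing.
"""

import numpy as np

import emsaxs as es

grid = np.indices((8, 8, 8)).reshape(3, -1).T * 2.0
weights = np.ones(len(grid))
q = np.linspace(0.01, 0.5, 50)

exact = es.debye_exact(grid, weights, q)
for weighted, name in ((False, "midpoint bins"), (True, "weighted bins")):
    hist = es.pair_histogram(grid, weights, bin_width=0.5, weighted_bins=weighted)
    err = np.max(np.abs(es.debye_intensity(hist, q) / exact - 1))
    print(f"{name:>14}: max relative intensity error {err:.2e}")
print("the weighted-bin error should be orders of magnitude smaller —")
print("that is what makes coarse 0.5 A bins usable on lattice models")
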