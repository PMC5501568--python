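"""Train a self-organizing map and inspect its U-matrix.

The U-matrix holds the distance between neighboring prototype vectors; a
ridge of large distances separates groups of similar field locations and
is how the number of zones is judged before K-means is applied.
"""

from dataclasses import replace

import numpy as np

import terrazone as tz
from terrazone.pipeline import build_features

cfg = replace(tz.SyntheticFieldConfig(), rows=40, cols=50, n_potholes=4)
dem, truth = tz.generate_dem(cfg, seed=7)
hh, vv = tz.generate_emi(dem, cfg, truth, seed=8)
_, fm_raw = build_features(dem, hh, vv)
fm = tz.normalize_features(fm_raw)

rows, cols = 12, 9
cb0 = tz.init_codebook(fm, rows, cols, seed=0)
cb = tz.train(cb0, fm, tz.TrainingSchedule.default(fm.n, rows, cols, seed=0))

print(f"SOM: {rows} x {cols} hexagonal lattice, {fm.n} inputs, k={fm.k}")
print(f"quantization error: init {tz.quantization_error(cb0, fm):.3f} -> "
      f"trained {tz.quantization_error(cb, fm):.3f}")

um = tz.compute_umatrix(cb)
edges = np.array([d for _, _, d in um.edges])
print(f"U-matrix edges: median {np.median(edges):.3f}, "
      f"max {edges.max():.3f} (a max >> median marks a zone boundary)")

# per-node mean neighbor distance, quantized to a small character map
chars = " .:-=+*#%@"
scaled = (um.node_values - um.node_values.min()) / np.ptp(um.node_values)
print("\nU-matrix (darker character = larger distance to neighbors):")
for r in range(rows):
    print("  " + "".join(chars[int(v * (len(chars) - 1))]
                         for v in scaled[r]))
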