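"""Sensitivity of the entropy indices to bin width and spatial resolution.

On 100 simulated plots, recomputes the LAI Pielou-yield correlation across
classification parameters (bin widths) and across GSD degradation factors,
reproducing the two qualitative trends the method exhibits: the signal
strengthens at fine bin widths and degrades with coarser pixels.
"""

import numpy as np

from wheatuniformity import (
    FieldSimConfig,
    bin_values,
    pielou_index,
    simulate_trait_raster,
    simulate_yield_table,
    sweep_bin_width,
    sweep_gsd,
)

cfg = FieldSimConfig(n_plots=100, seed=3)
rasters = {
    f"plot_{p:03d}": simulate_trait_raster(cfg, "LAI", p, stage="FS")
    for p in range(cfg.n_plots)
}
pj = np.array([pielou_index(bin_values(r.valid_values(), 0.5)) for r in rasters.values()])
mn = np.array([r.valid_values().mean() for r in rasters.values()])
outcomes = simulate_yield_table(cfg, pj, mn, plot_ids=sorted(rasters))

widths = (0.25, 0.5, 1.0, 1.5, 2.0, 2.5, 3.75, 5.0, 7.5)
bw = sweep_bin_width(rasters, outcomes, widths=widths)
print("classification parameter sweep (LAI Pielou vs yield):")
for w in widths:
    r = bw.r("pielou", w)
    print(f"  width {w:5.2f}: r = {'undefined (S=1)' if np.isnan(r) else f'{r:+.3f}'}")

gs = sweep_gsd(rasters, outcomes, factors=(1, 2, 4, 8))
print("\nspatial resolution sweep (LAI Pielou vs yield):")
for f in (1, 2, 4, 8):
    print(f"  GSD {cfg.gsd_m * f * 100:4.0f} cm: r = {gs.r('pielou', cfg.gsd_m * f):+.3f}")

print("\nCoarse bins collapse every plot into one class (entropy 0, r undefined);")
print("coarse pixels average away within-plot structure, weakening |r|.")
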