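"""Recover a hydration-shell radius with the global-scale interaction PRDF.

Waters are placed around hard-core osmolytes with 35% of them on a 4 Å
first hydration shell.  The global-scale interaction model connects each
osmolyte to every water (same-species distances are infinite), so the dim-0
barcode deaths are exactly the osmolyte-water distances and the
density-normalised death histogram is the osmolyte-water radial distribution
function: first peak at the shell radius, tail at 1.
"""

import numpy as np

import wph

osmo = wph.gen_hardcore(10, 30.0, min_dist=6.0, seed=5)
cfg = wph.gen_solvated(osmo, 600, shell_radius=4.0, shell_fraction=0.35,
                       jitter=0.3, seed=6)
traj = wph.gen_trajectory(cfg, n_frames=3, frame_jitter=0.2, seed=8)

curve = wph.global_prdf_pipeline(traj, bin_width=0.2)
peak = int(np.argmax(curve.values))
tail = curve.bin_centers >= 10.0
print(f"water number density (sphere-average rule): {curve.rho:.5f} / Å^3")
print(f"PRDF maximum {curve.values[peak]:.2f} at r = {curve.bin_centers[peak]:.2f} Å")
print(f"PRDF tail mean (r >= 10 Å): {curve.values[tail].mean():.3f}")
print(
    "\nThe maximum sits in the bin at the generator's 4 Å shell radius and the\n"
    "tail converges to 1, as for a conventional RDF of a uniform background."
)
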