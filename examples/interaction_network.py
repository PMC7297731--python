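"""Local-scale interaction analysis: Voronoi-like grouping without Voronoi.

In the local-scale interaction matrix all osmolytes and waters appear at
once, with same-species distances infinite.  As the filtration grows, waters
first join their nearest osmolyte (an implicit Voronoi-cell grouping), then
cells merge through shared waters.  The dim-0 deaths are the bipartite
minimum-spanning-forest edge weights; the local PRDF built from them decays
to zero, unlike the global-scale one.  Because any three points include a
same-species pair, no triangle ever forms: every 1-cycle persists forever.
"""

import numpy as np

import wph
from wph.iph import build_local_iph_matrix, iph_betti1_check

osmo = wph.gen_hardcore(8, 26.0, min_dist=6.0, seed=11)
cfg = wph.gen_solvated(osmo, 160, shell_radius=4.0, shell_fraction=0.4,
                       jitter=0.3, seed=12)
traj = wph.gen_trajectory(cfg, n_frames=5, frame_jitter=0.2, seed=13)

curve = wph.local_prdf_pipeline(traj, bin_width=0.2)
pbn, bpes = wph.iph_pbn_bpe_pipeline(traj)

print(f"local PRDF: largest death x_t = {curve.x_t:.2f} Å; "
      f"curve is 0 beyond it (max r with signal: "
      f"{curve.bin_centers[curve.values > 0].max():.2f} Å)")
print(f"dim-0 PBN at r=0: {pbn.values[0]:.0f} (= all {cfg.n_points} molecules)")
print(f"per-frame dim-0 BPE: mean {bpes.mean():.4f}, sd {bpes.std(ddof=1):.4f} "
      f"over {len(bpes)} frames")

report = iph_betti1_check(build_local_iph_matrix(traj[0]), verify_threshold=0)
print(f"bipartite structure confirmed analytically: {report['analytic_bipartite']} "
      "(no 2-simplex can ever form; all loops persist forever)")
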