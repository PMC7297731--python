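"""Distinguish even from clustered molecular distributions with local barcodes.

Two synthetic solute configurations with identical point count and box are
analysed with localized persistent homology: a 9 Å sphere is drawn around
every molecule and the dim-1 persistent Betti number (loop count vs
filtration radius) is averaged over all molecules and frames.  Evenly spread
(hard-core) molecules form large network circles; clustered molecules form
many small circles inside their clusters, so the clustered PBN peaks at a
distinctly smaller radius.
"""

import wph

BOX, N, CUTOFF = 30.0, 110, 9.0

hardcore = wph.gen_hardcore(N, BOX, min_dist=4.2, seed=101)
clustered = wph.gen_clustered(12, N / 12, sigma=1.2, box=BOX, seed=101, n_total=N)

for name, base in (("hard-core (even)", hardcore), ("clustered", clustered)):
    traj = wph.gen_trajectory(base, n_frames=3, frame_jitter=0.3, seed=7)
    curve = wph.lph_average_pbn(traj, wph.OSMOLYTE, cutoff=CUTOFF, k=1)
    bpe = wph.lph_bpe_series(traj, wph.OSMOLYTE, cutoff=CUTOFF, k=1)
    print(
        f"{name:18s} dim-1 PBN peak at {curve.peak_location():5.2f} Å "
        f"(height {curve.values.max():.3f}), mean BPE {bpe.mean():.4f}"
    )

print(
    "\nThe clustered system's loops live at ~2-3 Å (inside clusters) while the\n"
    "even system's loops live at ~6-8 Å (between neighbours): the peak location\n"
    "of the averaged dim-1 PBN separates the two aggregation regimes."
)
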