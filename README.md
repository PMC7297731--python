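# wph — weighted persistent homology for molecular aggregation

`wph` computes topological descriptors of coarse-grained molecular point
configurations in periodic orthorhombic boxes, of the kind produced by
molecular dynamics simulations of osmolyte solutions (TMAO, urea) in water.
It is aimed at researchers studying molecular aggregation, hydration
structure and hydrogen-bonding networks who want multiscale topological
summaries — how many clusters and loops exist at each distance scale, and how
regular their size distribution is — instead of, or alongside, classical
pair-correlation analysis.

## The models

All analyses are built on Vietoris–Rips persistent homology: a simplex enters
the filtration at the largest pairwise (minimum-image) distance among its
vertices, and each topological feature (connected component for β₀, loop for
β₁) is a bar [a, b) from its birth to its death radius.

Two *weighted* constructions restrict which points interact:

* **Localized persistent homology (LPH).** A sphere of cutoff radius R_c
  (defaults 9/12/15 Å for solutes, 7/9 Å for water) is drawn around every
  molecule; the Rips barcode of the enclosed points is computed up to
  filtration 2·R_c. Per-molecule descriptors are ensemble-averaged over all
  molecules and frames.
* **Interactive persistent homology (IPH).** The dissimilarity matrix sets
  same-species entries to ∞, so only osmolyte–water pairs connect. At the
  *global* scale (one osmolyte vs all N_w waters, a (N_w+1)×(N_w+1) matrix)
  the β₀ deaths are exactly the osmolyte–water distances; at the *local*
  scale (all N_s+N_w molecules at once) they are the bipartite
  minimum-spanning-forest edge weights. Since any vertex triple contains a
  same-species pair, no triangle ever forms and every β₁ bar persists
  forever.

Barcodes are condensed by four descriptors:

* **PBN** (persistent Betti number): f(x; L_k) = Σ_j χ_[a_j, b_j](x), the
  number of dimension-k bars alive at filtration value x.
* **PE** (persistent entropy): S_k = Σ −p_j ln p_j with
  p_j = (b_j − a_j) / Σ(b − a) over finite bars.
* **BPE** (Boltzmann persistent entropy): each bar carries a Betti energy
  E_j = α((b_j − a_j)/η)^κ (defaults α = k_BT, η = 1 Å, κ = 2) and
  p_j = e^(−E_j/k_BT)/Z, so longer bars get *lower* probability and the
  infinitely persisting bar gets exactly zero.
* **PRDF** (persistent radial distribution function): the density-normalised
  histogram of β₀ death radii, count/(4πr²Δr·ρ). For the global-scale IPH
  model this reproduces the conventional radial distribution function (first
  hydration peak near 4 Å, tail → 1); for the local-scale model it decays to
  zero past the largest merge distance.

Because MD trajectories are not shipped, a seeded generator module produces
the spatial regimes these descriptors distinguish: uniform, hard-core (even,
network-like), Thomas-process clustered, and solvated two-type configurations
with a tunable hydration shell.

## Worked example

`examples/local_topology.py` generates an even (hard-core) and a clustered
solute configuration at identical point count (110 points, 30 Å box),
runs the LPH pipeline at R_c = 9 Å, and prints:

```
hard-core (even)   dim-1 PBN peak at  7.90 Å (height 1.136), mean BPE 0.8728
clustered          dim-1 PBN peak at  2.90 Å (height 0.282), mean BPE 0.4644
```

Even spacing produces large network loops (β₁ peak near 8 Å); clustering
produces many small loops inside clusters (peak near 3 Å) — the peak location
of the averaged β₁ PBN cleanly separates the two aggregation regimes.
`examples/hydration_shell_rdf.py` does the same for the global-scale IPH
PRDF, recovering the generator's 4 Å hydration shell as the first peak
(`PRDF maximum 5.42 at r = 3.90 Å`) with the tail at 1; see also
`examples/barcode_basics.py` and `examples/interaction_network.py`.

A thin CLI mirrors the pipelines:

```bash
wph synth --kind solvated --n 10 --n-water 600 --box 30 --frames 3 --seed 1 --out data/
wph iph-global --input data/solvated.xyz --bin-width 0.2 --out results/
wph lph --input data/solvated.xyz --cutoff 9 --species WATER --out results/
```

Input formats: multi-frame XYZ (box on the comment line as `box=Lx,Ly,Lz` in
Å) and GROMACS GRO (nm, converted on read), with coarse-graining rules that
keep the TMAO nitrogen / urea carbon / water oxygen as one point per
molecule.

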