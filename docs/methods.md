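# Methods

## Geometry and periodicity

Configurations are n points in an orthorhombic box (lengths in Å), each
labelled `OSMOLYTE` or `WATER`. Coordinates are wrapped into [0, box_i) and
every distance is a minimum-image distance: per-axis displacements are
reduced into [−box_i/2, box_i/2] before taking the Euclidean norm. Triclinic
boxes are rejected — the target systems are cubic NPT boxes, and orthorhombic
minimum image is exact and cheap there.

Local regions are spheres of radius R_c around a center molecule, under the
precondition 2·R_c ≤ min(box) so each neighbour has a unique periodic image
inside the sphere; violating inputs raise instead of silently duplicating
images. The center is always a member of its own region, which makes the
degenerate one-point region well defined. Minimum-image distances are used
both for region membership and for the local distance matrix — the local
patch is never unwrapped into a flat chart, so a pair of members on opposite
sides of the sphere still gets its true periodic separation.

## Rips filtration and persistence

Only the Vietoris–Rips (flag) complex is used. An edge enters at the
pairwise distance d itself (not d/2), so barcode axes read directly in
inter-particle distances — hydrogen-bond-scale features appear near 3.5 Å,
matching the convention of the standard Rips software ecosystem. Simplices
are ordered by (value, dimension, vertex tuple); the lexicographic tie-break
makes every run deterministic. Complexes are built to simplex dimension
max_dim ∈ {1,2,3} and homology is reported for dimensions strictly below it
(a top-dimensional class cannot be killed without the next layer of
simplices, so reporting it would conflate "persists forever" with "killer
not built"). The default is a dimension-2 complex, i.e. β₀ and β₁; β₂ is
available but off by default.

Persistence is computed by GF(2) boundary-matrix column reduction with
columns held as integer bitmasks. Zero-persistence pairs (birth = death) are
dropped: they carry no information for any of the descriptors. Infinite
distance-matrix entries are first-class — such a pair simply never forms an
edge; there is no large-sentinel substitute. A union-find fast path computes
dimension-0 barcodes directly from the sorted finite edges (single-linkage
merge heights = minimum-spanning-forest edge weights) and is used by all
interaction-matrix pipelines, where materialising a Rips complex over
thousands of points would be wasteful; its output is tested to equal the
reduction path exactly. The maximum filtration value is an explicit
parameter: local regions use 2·R_c (the largest distance a region of radius
R_c can contain — truncating at R_c would clip real features), global frame
analyses default to half the box.

The test suite cross-checks the reduction against two independent oracles:
scipy's minimum spanning tree for dimension 0, and a rank-function oracle
that computes β^{i,j} = rank(H_k(K_i) → H_k(K_j)) by GF(2) linear algebra on
cycle and boundary spaces and recovers bar multiplicities by
inclusion–exclusion. The oracle shares no code with the implementation.

## Descriptors

**PBN.** f(x; L_k) counts bars with a_j ≤ x ≤ b_j, the indicator treated as a
closed interval exactly as defined, so a bar is counted at both endpoints.
Curves are evaluated on an explicit grid, by default 0 → max_filt in 0.1 Å
steps — fine enough to resolve the 3.5–4 Å structure the analyses target.

**PE.** Shannon entropy of normalised bar lengths over *finite* bars by
default. An `include_infinite` mode implements the limiting convention for
the ever-present infinite β₀ bar: as its length dominates, its probability
tends to exactly 1.0 and the entropy to 0, regardless of the finite bars.
This is kept as a documented mode rather than the default because an
identically-zero descriptor is useless in practice.

**BPE.** Betti energy E_j = α((b_j−a_j)/η)^κ with defaults α = k_BT,
η = 1 Å, κ = 2; probabilities are Boltzmann weights over finite bars,
normalised to sum to 1. With α = k_BT the ratio E/k_BT is
temperature-independent, so no numeric temperature is ever needed. Infinite
bars receive probability exactly 0 — an infinite length gives infinite
energy and vanishing weight. (The weighting is deliberately opposite to PE:
long bars are *improbable*.) An empty barcode, or one with no finite bar,
has PE = BPE = 0 by definition; sparse local regions at low concentration
hit this case constantly and must average cleanly. The softmax is computed
with the minimum energy subtracted, so large bars cannot underflow the
normalisation. Both entropies lie in [0, ln N_k], with equality iff all
finite bars have equal length.

**PRDF.** β₀ deaths are histogrammed in bins of width Δr (default 0.1 Å;
the pipelines in the examples use 0.2 Å to trade resolution for smoothness
at small sample sizes). The default "conventional" normalisation divides the
bin count by 4πr²Δr·ρ, which makes the global-scale curve a true RDF
estimator: tail → 1 on uniform data, independent of Δr. The written
definition with an x_t/N₀ prefactor and no density division is kept as the
"literal" mode, but it is dimensionally inconsistent with the RDF
equivalence and with a unit tail, so it is not the default. x_t (largest
finite death — the radius where the PBN reaches its floor) and N₀ (total
bar count) are reported on every curve. Histograms are cut at r_max =
min(box)/2: beyond half the box the spherical shell 4πr²Δr is no longer
contained in the box and the estimator is biased by construction.

## LPH pipeline

For each frame and each molecule of the selected species, the local region's
barcode is computed once and feeds both summaries: PBN curves are averaged
with equal weight per (molecule, frame) pair on a common grid (curves are
evaluated directly on the grid, no resampling); BPEs are averaged within
each frame, giving one value per frame — a 101-frame trajectory yields a
series of 101 BPEs whose mean and variance characterise topological
disorder and its fluctuation. A frame-subsampling utility selects F equally
spaced frames including the first and last (default F = 101).

## IPH pipeline

Global scale: one matrix per osmolyte per frame, (N_w+1)×(N_w+1). The β₀
deaths equal the osmolyte–water distance multiset (each water merges into
the center's component at exactly its distance), so the pipelines compute
the distance vectors directly and never materialise the matrices; the
matrix constructor exists for the API and is tested against the fast path.
The PRDF density uses the sphere-average rule: the mean number of waters
within r_max of an osmolyte divided by the r_max-sphere volume. Each
(osmolyte, frame) pair carries equal weight in the average — with a constant
osmolyte count this equals the per-frame-then-per-molecule average, and with
varying counts it weights every local environment equally, which is the
statistically natural choice for a pooled histogram.

Local scale: one matrix per frame over all molecules. Deaths are bipartite
MSF edge weights (Kruskal oracle in the tests); the density is simply
N_w/V. The Voronoi-like grouping of waters around their nearest osmolyte is
emergent in the filtration order and is never computed explicitly. Diagonal
entries are 0 so every molecule is born at filtration 0 (an all-∞ diagonal
would leave barcodes undefined). No β₁ bar of any interaction matrix can
die — any triangle needs three pairwise-finite edges, impossible with two
species — and `iph_betti1_check` both states this analytically and verifies
it by explicit reduction on small instances.

## Synthetic data

The generators replace MD trajectories and define the study conditions:

* `gen_uniform` — ideal-gas points; the null model for density checks.
* `gen_hardcore` — dart-throwing with minimum-image exclusion (default
  min_dist 4 Å, the coarse-grained near-neighbour scale); emulates the even,
  network-like solute regime. Fails loudly if the packing is infeasible.
* `gen_clustered` — Thomas process: uniform parents, Poisson broods,
  isotropic Gaussian spread (default σ 1.5 Å); emulates cluster-forming
  solutes. An optional fixed-total variant assigns each point a uniform
  random parent, for matched-n regime comparisons.
* `gen_solvated` — two-type configurations: a fraction of waters (default
  0.3) on a shell of radius 4 Å (the first hydration peak position) with
  0.3 Å Gaussian radial jitter around hard-core osmolytes, the rest uniform.
* `gen_trajectory` — a base configuration plus per-frame Gaussian jitter
  (wrapped), giving statistically stationary frames.

What these emulate — and do not. They reproduce the *spatial statistics* the
descriptors respond to (even vs clustered packing, a hydration shell, frame
decorrelation) but none of the physics: no molecular shape, no
hydrogen-bond geometry or orientation, no concentration-dependent box
relaxation, no temporal correlation beyond i.i.d. jitter. Tests passing on
this data demonstrate that the descriptors measure what they claim on known
ground truth; they do not re-derive any simulation-based observation about
real TMAO or urea.

Reference system sizes are 3000 waters with solute counts 63–887 (TMAO) or
60–681 (urea) per concentration in ~45 Å boxes; the shipped tests and
examples scale these down (tens to hundreds of solutes, up to 2000–3000
waters where the O(N_w·N_s) dim-0 path makes it cheap, 3–10 frames instead
of 101) while keeping densities in the same regime. The full 101-frame
averaging convention remains the default of the pipeline utilities.

## Numerical choices and edge cases

* Distance-matrix validation: symmetry to 1e−12, zero diagonal, symmetric
  infinity pattern; violations raise.
* Coincident points merge at filtration 0 with zero persistence and produce
  no bar; component counts still reflect the merge.
* Boltzmann normalisation is shift-stabilised (min energy subtracted).
* The PBN grid and PRDF bins are half-open constructions from integer
  multiples of the step, so curves from equal parameters are bit-identical
  across runs; all generator randomness flows through one seeded
  `numpy.random.Generator` per call, with no global state.
* 4 Å falls on a PRDF bin edge at the default widths; shell-recovery checks
  therefore accept the maximum in either bin touching 4 Å.

## Known limitations

* The column-reduction core targets local-region and small-frame problem
  sizes (hundreds of points); whole-box β₁ analyses of thousands of points
  would need a specialised persistence backend.
* Only orthorhombic boxes, and local cutoffs up to half the box edge.
* PRDF normalisation is untrustworthy beyond half the box and the curves
  are truncated there by design.
* The literal PRDF mode is provided for completeness but its scale is not
  comparable across system sizes.
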