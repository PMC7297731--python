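"""Localized persistent homology: per-molecule barcodes and ensemble averages.

A sphere of cutoff radius R_c is drawn around every molecule of the selected
species; the points inside it (minimum image) form a local region whose Rips
barcode is computed up to filtration 2*R_c, the largest pairwise distance the
sphere allows.  Per-molecule persistent Betti number curves are averaged over
all molecules of all frames; Boltzmann persistent entropies are averaged over
molecules within each frame, yielding one BPE value per frame.
"""

from __future__ import annotations

import numpy as np

from .descriptors import (
    EntropyParams,
    PBNCurve,
    boltzmann_persistent_entropy,
    default_grid,
    persistent_betti_number,
)
from .geometry import Configuration, extract_local_region, pairwise_distance_matrix
from .rips import Barcode, build_rips_filtration, compute_persistence
from .synthetic import Trajectory, subsample_frames

__all__ = [
    "LPHResult",
    "lph_barcode",
    "lph_average_pbn",
    "lph_bpe_series",
    "global_frame_barcode",
    "lph_analysis",
]


def lph_barcode(
    config: Configuration,
    center: int,
    cutoff: float,
    max_dim: int = 2,
    species: str | None = None,
) -> Barcode:
    """Barcode of the local region around ``center`` (filtration cap 2*R_c)."""
    region = extract_local_region(config, center, cutoff, species=species)
    filtration = build_rips_filtration(
        region.local_distance_matrix, max_dim=max_dim, max_filt=2.0 * cutoff
    )
    return compute_persistence(filtration)


def _species_centers(config: Configuration, species: str) -> np.ndarray:
    centers = config.indices_of(species)
    if centers.size == 0:
        raise ValueError(f"no points of species {species!r} in frame {config.frame_index}")
    return centers


def lph_average_pbn(
    traj: Trajectory,
    species: str,
    cutoff: float,
    k: int = 1,
    grid: np.ndarray | None = None,
    max_dim: int | None = None,
) -> PBNCurve:
    """Mean dimension-k PBN curve over all molecules of all frames."""
    if grid is None:
        grid = default_grid(2.0 * cutoff)
    if max_dim is None:
        max_dim = k + 1
    total = np.zeros(len(grid))
    count = 0
    for frame in traj:
        for center in _species_centers(frame, species):
            bc = lph_barcode(frame, int(center), cutoff, max_dim=max_dim, species=species)
            total += persistent_betti_number(bc, k, grid).values
            count += 1
    return PBNCurve(grid=np.asarray(grid, dtype=float), values=total / count, dim=k)


def lph_bpe_series(
    traj: Trajectory,
    species: str,
    cutoff: float,
    k: int = 1,
    params: EntropyParams | None = None,
    max_dim: int | None = None,
) -> np.ndarray:
    """One BPE per frame: the mean over that frame's molecules of the species.

    Local regions with no finite dimension-k bar contribute 0, so sparse
    low-concentration frames produce near-zero series.
    """
    params = params or EntropyParams()
    if max_dim is None:
        max_dim = k + 1
    series = []
    for frame in traj:
        vals = [
            boltzmann_persistent_entropy(
                lph_barcode(frame, int(c), cutoff, max_dim=max_dim, species=species),
                k,
                params,
            )
            for c in _species_centers(frame, species)
        ]
        series.append(float(np.mean(vals)))
    return np.asarray(series)


def global_frame_barcode(
    config: Configuration,
    species: str,
    max_dim: int = 2,
    max_filt: float | None = None,
) -> Barcode:
    """Whole-box barcode of one frame's species subset (no locality cutoff)."""
    idx = _species_centers(config, species)
    dist = pairwise_distance_matrix(config, idx)
    if max_filt is None:
        max_filt = float(np.min(config.box)) / 2.0
    filtration = build_rips_filtration(dist, max_dim=max_dim, max_filt=max_filt)
    return compute_persistence(filtration)


class LPHResult:
    """Bundle of the standard LPH outputs for one trajectory and species."""

    def __init__(self, average_pbn: PBNCurve, bpe_series: np.ndarray, molecule_counts: np.ndarray):
        if len(bpe_series) != len(molecule_counts):
            raise ValueError("BPE series and molecule counts must align per frame")
        self.average_pbn = average_pbn
        self.bpe_series = np.asarray(bpe_series)
        self.molecule_counts = np.asarray(molecule_counts, dtype=int)


def lph_analysis(
    traj: Trajectory,
    species: str,
    cutoff: float,
    k: int = 1,
    params: EntropyParams | None = None,
    n_frames: int | None = None,
) -> LPHResult:
    """Full LPH pipeline: subsample frames, average PBN, per-frame BPE series.

    A single pass computes every local barcode once and reuses it for both the
    PBN average and the BPE series.
    """
    params = params or EntropyParams()
    if n_frames is not None:
        traj = subsample_frames(traj, n_frames)
    grid = default_grid(2.0 * cutoff)
    max_dim = k + 1
    total = np.zeros(len(grid))
    n_curves = 0
    bpe_series = []
    counts = []
    for frame in traj:
        centers = _species_centers(frame, species)
        frame_bpes = []
        for c in centers:
            bc = lph_barcode(frame, int(c), cutoff, max_dim=max_dim, species=species)
            total += persistent_betti_number(bc, k, grid).values
            frame_bpes.append(boltzmann_persistent_entropy(bc, k, params))
            n_curves += 1
        bpe_series.append(float(np.mean(frame_bpes)))
        counts.append(len(centers))
    avg = PBNCurve(grid=grid, values=total / n_curves, dim=k)
    return LPHResult(avg, np.asarray(bpe_series), np.asarray(counts))
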