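"""Periodic-box geometry: configurations, minimum-image distances, local regions.

All lengths are in Å. Boxes are orthorhombic; coordinates are stored wrapped
into [0, box_i). Distances between points always use the minimum image
convention, i.e. each per-axis displacement is reduced into
[-box_i/2, box_i/2] before the Euclidean norm is taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

OSMOLYTE = "OSMOLYTE"
WATER = "WATER"

__all__ = [
    "OSMOLYTE",
    "WATER",
    "Configuration",
    "LocalRegion",
    "wrap_coordinates",
    "minimum_image_displacement",
    "minimum_image_distance",
    "pairwise_distance_matrix",
    "cross_distance_matrix",
    "extract_local_region",
]


@dataclass
class Configuration:
    """One frame of a coarse-grained point configuration.

    Parameters
    ----------
    coords : (n, 3) float array
        Cartesian coordinates in Å.
    box : (3,) float array
        Orthorhombic box edge lengths in Å.
    types : (n,) array of str
        Per-point species label, each ``OSMOLYTE`` or ``WATER``.
    frame_index : int
        Index of this frame within its trajectory.
    names : optional (n,) array of str
        Raw atom names (kept by the file readers for coarse-graining).
    resnames : optional (n,) array of str
        Raw residue names (kept by the file readers for coarse-graining).
    """

    coords: np.ndarray
    box: np.ndarray
    types: np.ndarray
    frame_index: int = 0
    names: np.ndarray | None = None
    resnames: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise ValueError("configuration must contain at least one point")
        if self.box.shape != (3,):
            raise ValueError(f"box must have 3 lengths, got shape {self.box.shape}")
        if not np.all(np.isfinite(self.box)) or np.any(self.box <= 0):
            raise ValueError(f"box lengths must be positive and finite: {self.box}")
        if not np.all(np.isfinite(self.coords)):
            bad = int(np.flatnonzero(~np.isfinite(self.coords).all(axis=1))[0])
            raise ValueError(f"non-finite coordinate at point index {bad}")
        self.types = np.asarray(self.types)
        if self.types.shape != (self.coords.shape[0],):
            raise ValueError("types must have one label per point")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    def indices_of(self, species: str) -> np.ndarray:
        """Indices of all points labelled ``species``."""
        return np.flatnonzero(self.types == species)

    def subset(self, indices: np.ndarray) -> "Configuration":
        """New configuration containing only the requested points."""
        indices = np.asarray(indices, dtype=int)
        return Configuration(
            coords=self.coords[indices],
            box=self.box.copy(),
            types=self.types[indices],
            frame_index=self.frame_index,
            names=None if self.names is None else np.asarray(self.names)[indices],
            resnames=None
            if self.resnames is None
            else np.asarray(self.resnames)[indices],
        )


@dataclass
class LocalRegion:
    """Spherical neighbourhood of one point under the minimum image convention."""

    center_index: int
    member_indices: np.ndarray
    local_distance_matrix: np.ndarray
    cutoff: float

    def __post_init__(self) -> None:
        self.member_indices = np.asarray(self.member_indices, dtype=int)
        self.local_distance_matrix = np.asarray(self.local_distance_matrix, dtype=float)
        if self.center_index not in self.member_indices:
            raise ValueError("center must be a member of its own local region")

    @property
    def size(self) -> int:
        return len(self.member_indices)


def wrap_coordinates(config: Configuration) -> Configuration:
    """Map every coordinate component into [0, box_i) by modular reduction."""
    wrapped = np.mod(config.coords, config.box)
    # mod can return box_i exactly for tiny negative inputs; fold those back
    wrapped = np.where(wrapped >= config.box, wrapped - config.box, wrapped)
    return replace(config, coords=wrapped)


def minimum_image_displacement(p: np.ndarray, q: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Per-axis displacement q→p reduced into [-box_i/2, box_i/2]."""
    box = np.asarray(box, dtype=float)
    d = np.asarray(p, dtype=float) - np.asarray(q, dtype=float)
    return d - box * np.round(d / box)


def minimum_image_distance(p, q, box) -> float:
    """Euclidean distance between p and q under the minimum image convention."""
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box lengths must be positive")
    return float(np.linalg.norm(minimum_image_displacement(p, q, box)))


def _min_image_cdist(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    d = a[:, None, :] - b[None, :, :]
    d -= box * np.round(d / box)
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))


def pairwise_distance_matrix(config: Configuration, subset=None) -> np.ndarray:
    """Symmetric minimum-image distance matrix for a subset of points.

    ``subset`` is an index collection; ``None`` means all points.
    """
    if subset is None:
        subset = np.arange(config.n_points)
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("subset must be non-empty")
    pts = config.coords[subset]
    mat = _min_image_cdist(pts, pts, config.box)
    np.fill_diagonal(mat, 0.0)
    return mat


def cross_distance_matrix(config: Configuration, rows, cols) -> np.ndarray:
    """Minimum-image distances between two index collections (rows × cols)."""
    rows = np.asarray(rows, dtype=int)
    cols = np.asarray(cols, dtype=int)
    return _min_image_cdist(config.coords[rows], config.coords[cols], config.box)


def extract_local_region(
    config: Configuration,
    center: int,
    cutoff: float,
    species: str | None = None,
) -> LocalRegion:
    """All points within ``cutoff`` of ``center`` (minimum image), plus the center.

    Requires 2*cutoff <= min(box) so every neighbour has a unique periodic
    image inside the sphere. If ``species`` is given, membership is restricted
    to that label (the center is always included regardless of its label).
    """
    if 2.0 * cutoff > float(np.min(config.box)):
        raise ValueError(
            f"2*cutoff = {2 * cutoff:g} exceeds the smallest box length "
            f"{np.min(config.box):g}; local spheres must fit in half the box"
        )
    if species is None:
        candidates = np.arange(config.n_points)
    else:
        candidates = config.indices_of(species)
    dists = _min_image_cdist(
        config.coords[[center]], config.coords[candidates], config.box
    )[0]
    members = candidates[dists <= cutoff]
    if center not in members:
        members = np.sort(np.append(members, center))
    mat = _min_image_cdist(config.coords[members], config.coords[members], config.box)
    np.fill_diagonal(mat, 0.0)
    return LocalRegion(
        center_index=center,
        member_indices=members,
        local_distance_matrix=mat,
        cutoff=cutoff,
    )
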