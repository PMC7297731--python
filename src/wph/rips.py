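"""Vietoris-Rips filtrations and persistence barcodes.

The filtration is the flag complex of the distance graph: a simplex enters at
the largest pairwise distance among its vertices, and an edge whose distance
exceeds the filtration cap (or is infinite) never enters, nor does any simplex
containing it.  Persistence is computed by standard boundary-matrix column
reduction over GF(2), with columns stored as Python integer bitmasks.  A
union-find fast path is provided for dimension 0, where persistence reduces to
single-linkage clustering: the finite death values are exactly the edge
weights of a minimum spanning forest of the finite-distance graph.

Dimension-k homology is reported for k up to (complex dimension - 1); bars of
the top built dimension cannot be closed without the next dimension of
simplices and are therefore not reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Simplex",
    "Filtration",
    "Barcode",
    "build_rips_filtration",
    "compute_persistence",
    "betti0_union_find",
    "simplices_at_filtration",
]


@dataclass(frozen=True)
class Simplex:
    """A simplex in a filtration: sorted vertex tuple and entry value (Å)."""

    vertices: tuple
    value: float

    @property
    def dim(self) -> int:
        return len(self.vertices) - 1


@dataclass
class Filtration:
    """Ordered Vietoris-Rips filtration.

    Simplices are sorted by (value, dimension, vertex tuple), which guarantees
    every face precedes its cofaces and gives a deterministic order.
    """

    simplices: list
    n_vertices: int
    max_dim: int
    max_filt: float

    def __len__(self) -> int:
        return len(self.simplices)


@dataclass
class Barcode:
    """Persistence bars grouped by homology dimension.

    ``bars[k]`` is an (m, 2) float array of (birth, death) pairs, death
    ``np.inf`` for features that never die.  Zero-persistence pairs are
    dropped at construction time by :func:`compute_persistence`.
    """

    bars: dict = field(default_factory=dict)
    max_homology_dim: int = 1

    def get(self, k: int) -> np.ndarray:
        """(m, 2) array of bars in dimension k (possibly empty)."""
        arr = self.bars.get(k)
        if arr is None:
            return np.empty((0, 2))
        return arr

    def finite(self, k: int) -> np.ndarray:
        """Bars of dimension k with finite death."""
        arr = self.get(k)
        return arr[np.isfinite(arr[:, 1])]

    def n_bars(self, k: int) -> int:
        """Total number of bars (finite and infinite) in dimension k."""
        return len(self.get(k))

    def n_infinite(self, k: int) -> int:
        arr = self.get(k)
        return int(np.sum(~np.isfinite(arr[:, 1])))

    @classmethod
    def from_pairs(cls, pairs_by_dim: dict, max_homology_dim: int | None = None) -> "Barcode":
        bars = {}
        for k, pairs in pairs_by_dim.items():
            arr = np.asarray(list(pairs), dtype=float).reshape(-1, 2)
            # canonical order: by birth, then death (inf last)
            order = np.lexsort((arr[:, 1], arr[:, 0]))
            bars[k] = arr[order]
        if max_homology_dim is None:
            max_homology_dim = max(bars, default=0)
        return cls(bars=bars, max_homology_dim=max_homology_dim)


def _validate_distmat(distmat: np.ndarray) -> np.ndarray:
    d = np.asarray(distmat, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"distance matrix must be square, got {d.shape}")
    finite = np.isfinite(d)
    if not np.array_equal(finite, finite.T):
        raise ValueError("distance matrix infinity pattern is asymmetric")
    if not np.allclose(d[finite & finite.T], d.T[finite & finite.T], atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if np.any(np.diagonal(d) != 0.0):
        raise ValueError("distance matrix diagonal must be zero")
    if np.any(d[finite] < 0):
        raise ValueError("distances must be non-negative")
    return d


def build_rips_filtration(
    distmat: np.ndarray, max_dim: int = 2, max_filt: float = math.inf
) -> Filtration:
    """Enumerate the Rips flag complex of ``distmat`` up to ``max_dim``.

    ``max_dim`` is the top *simplex* dimension built (1, 2 or 3); homology is
    then meaningful for dimensions strictly below it.  Infinite matrix entries
    mean "never connected": no simplex containing such a pair is created.
    """
    if max_dim not in (1, 2, 3):
        raise ValueError("max_dim must be 1, 2 or 3")
    d = _validate_distmat(distmat)
    n = d.shape[0]
    simplices = [Simplex((i,), 0.0) for i in range(n)]

    iu, ju = np.triu_indices(n, k=1)
    keep = np.isfinite(d[iu, ju]) & (d[iu, ju] <= max_filt)
    edges = list(zip(iu[keep].tolist(), ju[keep].tolist()))
    simplices.extend(Simplex((i, j), float(d[i, j])) for i, j in edges)

    if max_dim >= 2:
        adj = (np.isfinite(d) & (d <= max_filt)).astype(bool)
        np.fill_diagonal(adj, False)
        triangles = []
        for i, j in edges:
            common = np.flatnonzero(adj[i] & adj[j])
            for k in common[common > j]:
                k = int(k)
                val = max(d[i, j], d[i, k], d[j, k])
                triangles.append(Simplex((i, j, k), float(val)))
        simplices.extend(triangles)
        if max_dim >= 3:
            for t in triangles:
                i, j, k = t.vertices
                common = np.flatnonzero(adj[i] & adj[j] & adj[k])
                for l in common[common > k]:
                    l = int(l)
                    val = max(t.value, d[i, l], d[j, l], d[k, l])
                    simplices.append(Simplex((i, j, k, l), float(val)))

    simplices.sort(key=lambda s: (s.value, s.dim, s.vertices))
    return Filtration(simplices=simplices, n_vertices=n, max_dim=max_dim, max_filt=max_filt)


def compute_persistence(filtration: Filtration) -> Barcode:
    """Persistence barcode of a filtration by GF(2) column reduction.

    Returns bars for dimensions 0 .. max_dim-1.  Pairs with death == birth are
    discarded; creators never killed get death +inf.
    """
    simplices = filtration.simplices
    index_of = {s.vertices: i for i, s in enumerate(simplices)}
    top_report_dim = filtration.max_dim - 1

    columns: dict[int, int] = {}  # pivot -> reduced column bitmask
    column_owner: dict[int, int] = {}  # pivot -> index of column that holds it
    paired: set[int] = set()
    pairs: list[tuple[int, int]] = []  # (creator index, killer index)

    for j, s in enumerate(simplices):
        if s.dim == 0:
            continue
        col = 0
        verts = s.vertices
        for omit in range(len(verts)):
            face = verts[:omit] + verts[omit + 1:]
            col |= 1 << index_of[face]
        while col:
            pivot = col.bit_length() - 1
            other = columns.get(pivot)
            if other is None:
                break
            col ^= other
        if col:
            pivot = col.bit_length() - 1
            columns[pivot] = col
            column_owner[pivot] = j
            paired.add(pivot)
            paired.add(j)
            pairs.append((pivot, j))

    pairs_by_dim: dict[int, list] = {k: [] for k in range(top_report_dim + 1)}
    for creator, killer in pairs:
        k = simplices[creator].dim
        if k > top_report_dim:
            continue
        birth = simplices[creator].value
        death = simplices[killer].value
        if death > birth:
            pairs_by_dim[k].append((birth, death))
    for j, s in enumerate(simplices):
        if j not in paired and s.dim <= top_report_dim:
            pairs_by_dim[s.dim].append((s.value, math.inf))

    return Barcode.from_pairs(pairs_by_dim, max_homology_dim=top_report_dim)


def betti0_union_find(distmat: np.ndarray, max_filt: float = math.inf) -> Barcode:
    """Dimension-0 barcode by single-linkage union-find over finite edges.

    Agrees exactly (as a multiset of bars) with :func:`compute_persistence`:
    every point is born at 0 and the finite deaths are the merge heights,
    i.e. the minimum-spanning-forest edge weights of the finite-distance graph.
    """
    d = _validate_distmat(distmat)
    n = d.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = d[iu, ju]
    keep = np.isfinite(w) & (w <= max_filt)
    iu, ju, w = iu[keep], ju[keep], w[keep]
    order = np.argsort(w, kind="stable")

    parent = np.arange(n)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    deaths = []
    for e in order:
        a, b = find(int(iu[e])), find(int(ju[e]))
        if a != b:
            parent[max(a, b)] = min(a, b)
            if w[e] > 0:  # zero-weight merges are zero-persistence pairs: no bar
                deaths.append(float(w[e]))
    n_components = len({find(i) for i in range(n)})
    bars = [(0.0, dth) for dth in deaths] + [(0.0, math.inf)] * n_components
    return Barcode.from_pairs({0: bars}, max_homology_dim=0)


def simplices_at_filtration(filtration: Filtration, r: float, dims) -> list:
    """All simplices of the requested dimensions present at filtration value r."""
    if r > filtration.max_filt:
        raise ValueError(
            f"r = {r:g} exceeds the filtration cap {filtration.max_filt:g}"
        )
    dims = set(dims)
    return [s for s in filtration.simplices if s.dim in dims and s.value <= r]
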