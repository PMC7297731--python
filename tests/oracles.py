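"""Independent oracles for cross-checking the persistence implementation.

These deliberately avoid the code paths of the package:

* minimum-image distances by explicit enumeration of all 27 periodic images;
* dimension-0 deaths via scipy's minimum spanning tree (single linkage);
* component counts via scipy connected_components;
* full dimension-k diagrams via GF(2) rank functions of inclusion maps
  H_k(K_i) -> H_k(K_j), using the identity
      beta^{i,j} = rank([Z_k(i); B_k(j)]) - rank(B_k(j))
  and inclusion-exclusion over critical values to recover bar multiplicities.
  This is a mathematically distinct algorithm from boundary-matrix column
  reduction and never shares state with it.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree


def brute_force_min_image(p, q, box):
    """Min distance from p to any of the 27 periodic images of q."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    box = np.asarray(box, float)
    best = math.inf
    for sx, sy, sz in itertools.product((-1, 0, 1), repeat=3):
        img = q + np.array([sx, sy, sz]) * box
        best = min(best, float(np.linalg.norm(p - img)))
    return best


def _finite_graph(distmat):
    d = np.asarray(distmat, float)
    n = d.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    keep = np.isfinite(d[iu, ju])
    return n, iu[keep], ju[keep], d[iu[keep], ju[keep]]


def mst_deaths(distmat):
    """Sorted finite dim-0 death multiset = MST/forest edge weights (scipy)."""
    n, iu, ju, w = _finite_graph(distmat)
    # scipy drops explicit zeros; shift weights to keep zero-distance edges
    g = csr_matrix((w + 1.0, (iu, ju)), shape=(n, n))
    mst = minimum_spanning_tree(g)
    weights = np.asarray(mst[mst.nonzero()]).ravel() - 1.0
    return np.sort(weights[weights > 0])


def n_components_at(distmat, t):
    """Connected components of the graph with finite edges of weight <= t."""
    n, iu, ju, w = _finite_graph(distmat)
    keep = w <= t
    g = csr_matrix((np.ones(keep.sum()), (iu[keep], ju[keep])), shape=(n, n))
    return connected_components(g, directed=False)[0]


def n_components(distmat):
    return n_components_at(np.asarray(distmat, float), math.inf)


# ---------------------------------------------------------------- GF(2) tools


def gf2_rref(A):
    """Row echelon form over GF(2); returns (reduced matrix, pivot columns)."""
    A = (np.asarray(A) % 2).astype(np.uint8).copy()
    m, n = A.shape
    pivot_cols = []
    r = 0
    for c in range(n):
        if r >= m:
            break
        rows = np.flatnonzero(A[r:, c])
        if rows.size == 0:
            continue
        top = rows[0] + r
        if top != r:
            A[[r, top]] = A[[top, r]]
        mask = A[:, c].astype(bool)
        mask[r] = False
        A[mask] ^= A[r]
        pivot_cols.append(c)
        r += 1
    return A, pivot_cols


def gf2_rank(A):
    A = np.asarray(A)
    if A.size == 0:
        return 0
    return len(gf2_rref(A)[1])


def gf2_nullspace(A):
    """Basis (rows) of the null space of A over GF(2)."""
    A = np.asarray(A)
    m, n = A.shape
    if n == 0:
        return np.zeros((0, 0), np.uint8)
    if m == 0:
        return np.eye(n, dtype=np.uint8)
    R, piv = gf2_rref(A)
    free = [c for c in range(n) if c not in piv]
    basis = np.zeros((len(free), n), np.uint8)
    for row, f in enumerate(free):
        basis[row, f] = 1
        for i, c in enumerate(piv):
            if R[i, f]:
                basis[row, c] = 1
    return basis


# ------------------------------------------------- rank-function diagram oracle


def _rips_simplices(d, dim):
    """(simplex tuple, value) for all simplices of the given dimension."""
    n = d.shape[0]
    out = []
    for verts in itertools.combinations(range(n), dim + 1):
        vals = [d[a, b] for a, b in itertools.combinations(verts, 2)]
        value = max(vals) if vals else 0.0
        if math.isfinite(value):
            out.append((verts, value))
    out.sort(key=lambda s: (s[1], s[0]))
    return out


def rank_function_diagram(distmat, k):
    """Dimension-k persistence diagram via GF(2) ranks of inclusion maps.

    Returns (finite_bars, n_infinite): finite_bars is a sorted list of
    (birth, death) pairs with death > birth (zero-persistence pairs excluded
    by construction because critical values are distinct).
    """
    d = np.asarray(distmat, float)
    ksimp = _rips_simplices(d, k)
    faces = _rips_simplices(d, k - 1) if k >= 1 else []
    cofaces = _rips_simplices(d, k + 1)

    crit = sorted({0.0} | {v for _, v in ksimp} | {v for _, v in cofaces})
    m = len(crit)

    # boundary of k-simplices in the (k-1)-simplex basis
    face_index = {s: i for i, (s, _) in enumerate(faces)}
    n_k = len(ksimp)
    if k >= 1:
        bd_k = np.zeros((len(faces), n_k), np.uint8)
        for col, (verts, _) in enumerate(ksimp):
            for omit in range(len(verts)):
                bd_k[face_index[verts[:omit] + verts[omit + 1:]], col] = 1
    else:
        bd_k = np.zeros((0, n_k), np.uint8)

    k_index = {s: i for i, (s, _) in enumerate(ksimp)}
    bd_k1_cols = []
    for verts, value in cofaces:
        col = np.zeros(n_k, np.uint8)
        for omit in range(len(verts)):
            col[k_index[verts[:omit] + verts[omit + 1:]]] = 1
        bd_k1_cols.append((value, col))

    k_values = np.array([v for _, v in ksimp])
    # cycle bases Z_k(i) and echelonised boundary spaces B_k(j), per critical value
    Z, B, B_rank = [], [], []
    for r in crit:
        present = int(np.searchsorted(k_values, r, side="right"))
        null = gf2_nullspace(bd_k[:, :present])
        full = np.zeros((null.shape[0], n_k), np.uint8)
        if null.size:
            full[:, :present] = null
        Z.append(full)
        bcols = [c for v, c in bd_k1_cols if v <= r]
        Bmat = np.array(bcols, np.uint8).reshape(len(bcols), n_k)
        B.append(Bmat)
        B_rank.append(gf2_rank(Bmat))

    def beta(i, j):
        if i < 0:
            return 0
        stacked = np.vstack([Z[i], B[j]]) if B[j].size else Z[i]
        return gf2_rank(stacked) - B_rank[j]

    beta_cache = {}

    def betac(i, j):
        if (i, j) not in beta_cache:
            beta_cache[(i, j)] = beta(i, j)
        return beta_cache[(i, j)]

    finite = []
    for j in range(1, m):
        for i in range(j):
            mult = (betac(i, j - 1) - betac(i, j)) - (betac(i - 1, j - 1) - betac(i - 1, j))
            finite.extend([(crit[i], crit[j])] * mult)
    # infinite bars: classes still alive in the final complex, counted by birth
    last = m - 1
    n_inf = sum(betac(i, last) - betac(i - 1, last) for i in range(m))
    return sorted(finite), n_inf


def bipartite_mst_deaths(distmat, types):
    """Finite dim-0 deaths of an interaction matrix: Kruskal over cross-type edges."""
    d = np.asarray(distmat, float)
    types = np.asarray(types)
    n = d.shape[0]
    edges = [
        (d[i, j], i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if types[i] != types[j] and math.isfinite(d[i, j])
    ]
    edges.sort()
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    deaths = []
    for w, i, j in edges:
        a, b = find(i), find(j)
        if a != b:
            parent[a] = b
            if w > 0:
                deaths.append(w)
    return np.sort(deaths)
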