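"""Barcode summaries: persistent Betti numbers, entropies, and the PRDF.

Four descriptors are computed from a persistence barcode:

* the persistent Betti number (PBN) curve f(x; L_k) = sum_j chi_[a_j, b_j](x),
  counting the bars alive at filtration value x (closed interval, so a bar is
  counted at both its birth and its death value);
* the traditional persistent entropy (PE), the Shannon entropy of bar lengths
  normalised to probabilities p_j = (b_j - a_j) / sum(b - a);
* the Boltzmann persistent entropy (BPE), where each bar of length l carries a
  Betti energy E = alpha * (l / eta)**kappa and the probabilities are Boltzmann
  weights exp(-E / kBT) / Z, so that *longer* bars get *lower* probability —
  the opposite weighting to traditional PE;
* the persistent radial distribution function (PRDF), a density-normalised
  histogram of dimension-0 death radii.  In "conventional" mode the histogram
  count in the bin at radius r is divided by 4*pi*r^2*dr*rho, which for the
  global-scale interaction model reproduces the conventional RDF and makes the
  large-r tail converge to 1 for uniform data.  The "literal" mode instead
  applies the prefactor x_t / N_0 and no density division; it is kept as an
  explicit option but is not dimensionally consistent with an RDF tail of 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .rips import Barcode

__all__ = [
    "EntropyParams",
    "PBNCurve",
    "PRDFCurve",
    "persistent_betti_number",
    "max_finite_death",
    "persistent_entropy",
    "betti_energy",
    "boltzmann_probabilities",
    "boltzmann_persistent_entropy",
    "prdf_from_barcode",
    "default_grid",
]


@dataclass(frozen=True)
class EntropyParams:
    """Betti-energy parameters E = alpha * (length / eta)**kappa.

    Defaults follow the convention alpha = kBT, eta = 1 Å, kappa = 2, under
    which E / kBT = length**2 and the temperature never needs a numeric value.
    alpha and kBT are in the same (arbitrary) energy unit.
    """

    alpha: float = 1.0
    eta: float = 1.0
    kappa: int = 2
    kBT: float = 1.0

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.kappa < 1:
            raise ValueError("kappa must be a positive integer")
        if self.alpha <= 0 or self.kBT <= 0:
            raise ValueError("alpha and kBT must be positive")


@dataclass
class PBNCurve:
    """Persistent Betti number curve on an evaluation grid (Å)."""

    grid: np.ndarray
    values: np.ndarray
    dim: int

    def peak_location(self) -> float:
        """Grid value of the curve maximum (first occurrence on ties)."""
        return float(self.grid[int(np.argmax(self.values))])


@dataclass
class PRDFCurve:
    """Binned, density-normalised death-radius histogram."""

    bin_centers: np.ndarray
    values: np.ndarray
    x_t: float
    n0: int
    rho: float
    bin_width: float
    mode: str = "conventional"


def default_grid(max_filt: float, step: float = 0.1) -> np.ndarray:
    """Evaluation grid 0..max_filt inclusive with the given step (Å)."""
    n = int(round(max_filt / step))
    return np.linspace(0.0, n * step, n + 1)


def persistent_betti_number(barcode: Barcode, k: int, grid: np.ndarray) -> PBNCurve:
    """Count of dimension-k bars alive at each grid value (closed intervals)."""
    grid = np.asarray(grid, dtype=float)
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly ascending")
    bars = barcode.get(k)
    values = np.zeros(grid.shape)
    if len(bars):
        births = bars[:, 0][:, None]
        deaths = bars[:, 1][:, None]
        values = np.sum((births <= grid[None, :]) & (grid[None, :] <= deaths), axis=0)
    return PBNCurve(grid=grid, values=values.astype(float), dim=k)


def max_finite_death(barcode: Barcode, k: int) -> float:
    """x_t: the largest finite death value in dimension k."""
    finite = barcode.finite(k)
    if len(finite) == 0:
        raise ValueError(f"no finite bars in dimension {k}")
    return float(np.max(finite[:, 1]))


def persistent_entropy(
    barcode: Barcode, k: int, include_infinite: bool = False
) -> float:
    """Traditional persistent entropy S_k = sum_j -p_j ln p_j over bar lengths.

    With ``include_infinite`` the infinitely persisting bar dominates in the
    limit: it takes probability exactly 1.0 and every finite bar probability 0,
    so the entropy is 0 whenever an infinite bar is present.  An empty barcode
    has entropy 0 by definition (degenerate local regions contribute nothing).
    """
    if include_infinite and barcode.n_infinite(k) > 0:
        return 0.0
    finite = barcode.finite(k)
    if len(finite) == 0:
        return 0.0
    lengths = finite[:, 1] - finite[:, 0]
    lengths = lengths[lengths > 0]
    if lengths.size == 0:
        return 0.0
    p = lengths / lengths.sum()
    return float(-np.sum(p * np.log(p)))


def betti_energy(birth: float, death: float, params: EntropyParams | None = None) -> float:
    """Betti energy E = alpha * ((death - birth) / eta)**kappa; +inf for infinite bars."""
    params = params or EntropyParams()
    if math.isinf(death):
        return math.inf
    if death < birth:
        raise ValueError("death must be >= birth")
    return params.alpha * ((death - birth) / params.eta) ** params.kappa


def boltzmann_probabilities(
    barcode: Barcode, k: int, params: EntropyParams | None = None
) -> np.ndarray:
    """Boltzmann probabilities per bar of dimension k, in barcode order.

    Finite bars get p_j = exp(-E_j/kBT) / Z normalised over finite bars;
    infinite bars get exactly 0 (their Boltzmann weight vanishes).
    """
    params = params or EntropyParams()
    bars = barcode.get(k)
    if len(bars) == 0:
        raise ValueError(f"no bars in dimension {k}")
    finite_mask = np.isfinite(bars[:, 1])
    if not np.any(finite_mask):
        raise ValueError(f"no finite bars in dimension {k}")
    lengths = bars[finite_mask, 1] - bars[finite_mask, 0]
    energy_over_kBT = (params.alpha / params.kBT) * (lengths / params.eta) ** params.kappa
    # subtract the minimum for numerical stability; Z is invariant to the shift
    w = np.exp(-(energy_over_kBT - energy_over_kBT.min()))
    p = np.zeros(len(bars))
    p[finite_mask] = w / w.sum()
    return p


def boltzmann_persistent_entropy(
    barcode: Barcode, k: int, params: EntropyParams | None = None
) -> float:
    """BPE: Shannon entropy of the Boltzmann probabilities over finite bars.

    Empty barcodes (or barcodes with no finite bar) have BPE 0 by definition,
    so sparse local regions with no dimension-k feature contribute zero.
    """
    bars = barcode.get(k)
    if len(bars) == 0 or len(barcode.finite(k)) == 0:
        return 0.0
    p = boltzmann_probabilities(barcode, k, params)
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def prdf_from_barcode(
    barcode0: Barcode,
    bin_width: float = 0.1,
    rho: float | None = None,
    mode: str = "conventional",
    r_max: float | None = None,
) -> PRDFCurve:
    """PRDF from a dimension-0 barcode: histogram of death radii, normalised.

    conventional: value(bin at r) = count / (4 pi r^2 dr rho), the RDF
    estimator (requires ``rho``).  literal: count * (x_t / N_0) / (4 pi r^2),
    no density division.  ``r_max`` caps the histogram range; deaths beyond it
    are discarded (shell volumes are meaningless past half the box).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if mode not in ("conventional", "literal"):
        raise ValueError(f"unknown PRDF mode: {mode!r}")
    finite = barcode0.finite(0)
    if len(finite) == 0:
        raise ValueError("PRDF requires at least one finite dim-0 bar")
    deaths = finite[:, 1]
    x_t = float(deaths.max())
    n0 = barcode0.n_bars(0)
    top = r_max if r_max is not None else x_t
    n_bins = max(1, int(math.ceil(top / bin_width - 1e-9)))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(deaths, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * math.pi * centers**2
    if mode == "conventional":
        if rho is None or rho <= 0:
            raise ValueError("conventional PRDF requires a positive density rho")
        values = counts / (shell * bin_width * rho)
    else:
        values = counts * (x_t / n0) / shell
    return PRDFCurve(
        bin_centers=centers,
        values=values,
        x_t=x_t,
        n0=n0,
        rho=float(rho) if rho else float("nan"),
        bin_width=bin_width,
        mode=mode,
    )
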