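"""Seeded point-configuration generators standing in for MD trajectories.

Four spatial regimes are produced, matching the qualitative regimes the
topological descriptors are meant to distinguish:

UNIFORM   - ideal-gas points, the null model for density normalisation;
HARDCORE  - dart-throwing with a minimum-image exclusion distance, emulating
            an evenly distributed, network-like solute (TMAO-like);
CLUSTERED - a Thomas-type parent/offspring process, emulating solutes that
            concentrate into local clusters (urea-like);
SOLVATED  - a two-type osmolyte+water system where a fraction of waters sit
            on a first hydration shell (default radius 4 Å) around osmolytes,
            giving the global-scale PRDF its first peak near 4 Å.

All randomness flows through a single numpy Generator seeded explicitly;
identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import OSMOLYTE, WATER, Configuration, wrap_coordinates, _min_image_cdist

__all__ = [
    "GeneratorSpec",
    "Trajectory",
    "gen_uniform",
    "gen_hardcore",
    "gen_clustered",
    "gen_solvated",
    "gen_trajectory",
    "generate",
    "subsample_frames",
]


@dataclass
class Trajectory:
    """An ordered collection of configuration frames plus run metadata."""

    frames: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("trajectory must contain at least one frame")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative description of a synthetic configuration.

    kind: UNIFORM | HARDCORE | CLUSTERED | SOLVATED.  Only the parameters
    relevant to the chosen kind are read.
    """

    kind: str
    n: int = 100
    box: float = 40.0
    seed: int = 0
    min_dist: float = 4.0          # HARDCORE exclusion diameter
    n_parents: int = 10            # CLUSTERED
    offspring_mean: float = 10.0   # CLUSTERED
    sigma: float = 1.5             # CLUSTERED offspring spread
    n_osmolytes: int = 20          # SOLVATED
    n_water: int = 2000            # SOLVATED
    shell_radius: float = 4.0      # SOLVATED first hydration shell (Å)
    shell_fraction: float = 0.3    # SOLVATED fraction of waters on the shell
    jitter: float = 0.3            # SOLVATED radial jitter (Å)
    osmolyte_min_dist: float = 6.0  # SOLVATED osmolyte exclusion


def _box3(box) -> np.ndarray:
    b = np.asarray(box, dtype=float)
    if b.ndim == 0:
        b = np.repeat(b, 3)
    if b.shape != (3,) or np.any(b <= 0):
        raise ValueError("box must be a positive length or 3 positive lengths")
    return b


def gen_uniform(n: int, box, seed: int, species: str = OSMOLYTE) -> Configuration:
    """n points independently uniform in the periodic box."""
    if n < 1:
        raise ValueError("n must be >= 1")
    b = _box3(box)
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, 1.0, size=(n, 3)) * b
    return Configuration(coords=coords, box=b, types=np.full(n, species))


def gen_hardcore(
    n: int,
    box,
    min_dist: float,
    seed: int,
    species: str = OSMOLYTE,
    max_attempts_per_point: int = 500,
) -> Configuration:
    """Dart-throwing: uniform proposals rejected within ``min_dist`` (min image).

    Produces an even, network-like distribution.  Raises if the requested
    packing cannot be reached within the attempt budget.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    b = _box3(box)
    rng = np.random.default_rng(seed)
    placed = np.empty((0, 3))
    attempts = 0
    budget = max_attempts_per_point * n
    while len(placed) < n:
        if attempts >= budget:
            raise RuntimeError(
                f"hard-core packing failed: placed {len(placed)}/{n} points after "
                f"{budget} attempts; reduce n or min_dist, or enlarge the box"
            )
        p = rng.uniform(0.0, 1.0, size=(1, 3)) * b
        attempts += 1
        if len(placed) and np.min(_min_image_cdist(p, placed, b)) < min_dist:
            continue
        placed = np.vstack([placed, p])
    return Configuration(coords=placed, box=b, types=np.full(n, species))


def gen_clustered(
    n_parents: int,
    offspring_mean: float,
    sigma: float,
    box,
    seed: int,
    species: str = OSMOLYTE,
    n_total: int | None = None,
) -> Configuration:
    """Thomas-type cluster process: Gaussian offspring around uniform parents.

    By default each parent draws a Poisson(offspring_mean) brood, so the total
    count is random.  With ``n_total`` the count is fixed: each of the n_total
    offspring picks a uniformly random parent, preserving the clustered
    geometry at an exactly matched point count.
    """
    if n_parents < 1:
        raise ValueError("n_parents must be >= 1")
    b = _box3(box)
    rng = np.random.default_rng(seed)
    parents = rng.uniform(0.0, 1.0, size=(n_parents, 3)) * b
    if n_total is None:
        counts = rng.poisson(offspring_mean, size=n_parents)
        if counts.sum() == 0:
            counts[rng.integers(n_parents)] = 1
        assignment = np.repeat(np.arange(n_parents), counts)
    else:
        if n_total < 1:
            raise ValueError("n_total must be >= 1")
        assignment = rng.integers(0, n_parents, size=n_total)
    coords = parents[assignment] + rng.normal(0.0, sigma, size=(len(assignment), 3))
    cfg = Configuration(
        coords=np.mod(coords, b), box=b, types=np.full(len(assignment), species)
    )
    return wrap_coordinates(cfg)


def gen_solvated(
    osmolyte_config: Configuration,
    n_water: int,
    shell_radius: float = 4.0,
    shell_fraction: float = 0.3,
    jitter: float = 0.3,
    seed: int = 0,
) -> Configuration:
    """Waters around given osmolytes, a fraction on a first hydration shell.

    Each shell water picks a random osmolyte and a random direction, and sits
    at shell_radius plus Gaussian radial jitter; the remaining waters are
    uniform.  The returned configuration is the typed union osmolytes+waters.
    """
    if osmolyte_config.n_points < 1:
        raise ValueError("osmolyte configuration must be non-empty")
    if not 0.0 <= shell_fraction <= 1.0:
        raise ValueError("shell_fraction must be in [0, 1]")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    b = osmolyte_config.box
    rng = np.random.default_rng(seed)
    n_shell = int(round(shell_fraction * n_water))
    waters = []
    if n_shell:
        owners = rng.integers(0, osmolyte_config.n_points, size=n_shell)
        dirs = rng.normal(size=(n_shell, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        radii = shell_radius + rng.normal(0.0, jitter, size=n_shell) if jitter else np.full(n_shell, shell_radius)
        waters.append(osmolyte_config.coords[owners] + dirs * radii[:, None])
    if n_water - n_shell:
        waters.append(rng.uniform(0.0, 1.0, size=(n_water - n_shell, 3)) * b)
    water_coords = np.mod(np.vstack(waters), b) if waters else np.empty((0, 3))
    coords = np.vstack([osmolyte_config.coords, water_coords])
    types = np.concatenate(
        [osmolyte_config.types, np.full(len(water_coords), WATER)]
    )
    return wrap_coordinates(Configuration(coords=coords, box=b, types=types))


def generate(spec: GeneratorSpec) -> Configuration:
    """Build the configuration a GeneratorSpec describes."""
    kind = spec.kind.upper()
    if kind == "UNIFORM":
        return gen_uniform(spec.n, spec.box, spec.seed)
    if kind == "HARDCORE":
        return gen_hardcore(spec.n, spec.box, spec.min_dist, spec.seed)
    if kind == "CLUSTERED":
        return gen_clustered(
            spec.n_parents, spec.offspring_mean, spec.sigma, spec.box, spec.seed,
            n_total=spec.n if spec.n else None,
        )
    if kind == "SOLVATED":
        osmo = gen_hardcore(
            spec.n_osmolytes, spec.box, spec.osmolyte_min_dist, spec.seed
        )
        return gen_solvated(
            osmo, spec.n_water, spec.shell_radius, spec.shell_fraction,
            spec.jitter, spec.seed + 1,
        )
    raise ValueError(f"unknown generator kind: {spec.kind!r}")


def gen_trajectory(
    base,
    n_frames: int,
    frame_jitter: float = 0.0,
    seed: int = 0,
) -> Trajectory:
    """Stationary trajectory: a base configuration plus per-frame Gaussian jitter.

    ``base`` is either a Configuration or a GeneratorSpec (realised first).
    frame 0 is the base itself when frame_jitter is 0; every frame is wrapped.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if isinstance(base, GeneratorSpec):
        base = generate(base)
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_frames):
        coords = base.coords
        if frame_jitter > 0:
            coords = coords + rng.normal(0.0, frame_jitter, size=coords.shape)
        cfg = wrap_coordinates(
            Configuration(
                coords=coords, box=base.box, types=base.types.copy(), frame_index=i
            )
        )
        frames.append(cfg)
    return Trajectory(frames=frames, metadata={"frame_jitter": frame_jitter, "seed": seed})


def subsample_frames(traj: Trajectory, n_frames: int = 101) -> Trajectory:
    """Select n_frames equally spaced frames including the first and the last."""
    total = len(traj)
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if n_frames >= total:
        return traj
    idx = np.unique(np.round(np.linspace(0, total - 1, n_frames)).astype(int))
    return Trajectory(frames=[traj.frames[i] for i in idx], metadata=dict(traj.metadata))
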