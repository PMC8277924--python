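"""Genetic-algorithm global search over ion–water cluster geometries.

Lamarckian cluster GA: every candidate is locally relaxed before it
competes, the pool keeps only deduplicated local minima sorted by
energy, and the best entry never worsens (elitism).  Recombination is
the cut-and-splice operator standard for atomic/molecular clusters: a
random plane through the ion cuts both parents and complementary halves
are joined.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .geometry import (
    ClusterGeometry,
    InvalidGeometryError,
    MIN_ION_O_DISTANCE,
    MIN_OO_DISTANCE,
    WaterMolecule,
    random_rotation_matrix,
)
from .potential import EnergyModel, MinimizationError, local_minimize

logger = logging.getLogger(__name__)

__all__ = [
    "GAConfig",
    "MinimaPool",
    "PoolEntry",
    "PlacementError",
    "OperatorFailure",
    "init_population",
    "random_cluster",
    "crossover_cut_splice",
    "mutate",
    "is_duplicate",
    "evolve",
    "MUTATION_OPERATORS",
]

MUTATION_OPERATORS = ("rotate_water", "shell_hop", "twist")


class PlacementError(RuntimeError):
    """Could not place a water without overlap; try larger radius bounds."""


class OperatorFailure(RuntimeError):
    """A crossover/mutation product could not be repaired to validity."""


@dataclass(frozen=True)
class GAConfig:
    """GA control parameters (all overridable; defaults are the shipped ones)."""

    population_size: int = 16
    max_generations: int = 400
    stall_generations: int = 60
    crossover_probability: float = 0.8
    mutation_weights: Mapping[str, float] = field(
        default_factory=lambda: {op: 1.0 for op in MUTATION_OPERATORS}
    )
    dedup_energy_tol: float = 1e-3      # kJ/mol
    dedup_fingerprint_tol: float = 0.05  # Å
    rng_seed: int = 0
    initial_radius_bounds: tuple[float, float] = (2.2, 5.5)
    gtol: float = 1e-4
    minimize_max_iter: int = 2000

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        if not 0.0 <= self.crossover_probability <= 1.0:
            raise ValueError("crossover_probability must be a fraction")
        if self.dedup_energy_tol <= 0 or self.dedup_fingerprint_tol <= 0:
            raise ValueError("dedup tolerances must be positive")
        w = dict(self.mutation_weights)
        unknown = set(w) - set(MUTATION_OPERATORS)
        if unknown:
            raise ValueError(f"unknown mutation operators: {sorted(unknown)}")
        if any(v < 0 for v in w.values()) or sum(w.values()) <= 0:
            raise ValueError("mutation weights must be nonnegative, not all zero")
        lo, hi = self.initial_radius_bounds
        if not (MIN_ION_O_DISTANCE <= lo < hi):
            raise ValueError("bad initial_radius_bounds")
        object.__setattr__(self, "mutation_weights", dict(w))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mutation_weights"] = dict(self.mutation_weights)
        d["initial_radius_bounds"] = list(self.initial_radius_bounds)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "GAConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown GA config keys: {sorted(unknown)}")
        if "initial_radius_bounds" in data:
            data["initial_radius_bounds"] = tuple(data["initial_radius_bounds"])
        return cls(**data)


@dataclass(frozen=True)
class PoolEntry:
    geometry: ClusterGeometry
    energy: float
    generation: int


class MinimaPool:
    """Energy-sorted, deduplicated pool of locally minimized geometries."""

    def __init__(self, config: GAConfig):
        self.config = config
        self.entries: list[PoolEntry] = []
        self.best_trace: list[float] = []

    @property
    def best(self) -> PoolEntry:
        return self.entries[0]

    def __len__(self) -> int:
        return len(self.entries)

    def insert(self, geometry: ClusterGeometry, energy: float, generation: int) -> bool:
        """Insert unless duplicate of an existing entry; keep sorted; truncate."""
        for e in self.entries:
            if is_duplicate(geometry, e.geometry, energy, e.energy, self.config):
                return False
        self.entries.append(PoolEntry(geometry, energy, generation))
        self.entries.sort(key=lambda e: e.energy)
        del self.entries[self.config.population_size :]
        return True


# ----------------------------------------------------------------------
# construction of random candidates
# ----------------------------------------------------------------------
def make_water(
    oxygen: np.ndarray,
    rotation: np.ndarray,
    r_oh: float = 1.0,
    theta: float = np.deg2rad(109.47),
) -> WaterMolecule:
    """Water at ``oxygen`` with orientation given by a rotation matrix."""
    half = theta / 2.0
    h1 = np.array([np.cos(half), np.sin(half), 0.0]) * r_oh
    h2 = np.array([np.cos(half), -np.sin(half), 0.0]) * r_oh
    return WaterMolecule(oxygen, oxygen + np.array([rotation @ h1, rotation @ h2]))


def random_cluster(
    n: int,
    rng: np.random.Generator,
    radius_bounds: tuple[float, float] = (2.2, 5.5),
    max_rejections: int = 1000,
) -> ClusterGeometry:
    """Ion at the origin, n randomly placed and oriented waters.

    Oxygen directions are uniform on the sphere, radii uniform in
    ``radius_bounds``; placements overlapping an existing oxygen
    (O–O < 1.8 Å) or the ion are rejected.
    """
    oxygens: list[np.ndarray] = []
    waters: list[WaterMolecule] = []
    for _ in range(n):
        for _attempt in range(max_rejections):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            pos = rng.uniform(*radius_bounds) * u
            if all(
                np.linalg.norm(pos - q) >= MIN_OO_DISTANCE for q in oxygens
            ) and np.linalg.norm(pos) >= MIN_ION_O_DISTANCE:
                break
        else:
            raise PlacementError(
                f"failed to place water after {max_rejections} rejections; "
                "increase initial_radius_bounds"
            )
        oxygens.append(pos)
        waters.append(make_water(pos, random_rotation_matrix(rng)))
    return ClusterGeometry(np.zeros(3), 2, waters)


def init_population(
    n: int,
    config: GAConfig,
    model: EnergyModel,
    rng: np.random.Generator | None = None,
    seed_geometries: Sequence[ClusterGeometry] = (),
) -> MinimaPool:
    """Build the generation-0 pool of minimized random structures.

    ``seed_geometries`` (e.g. read from XYZ files of earlier runs) are
    minimized and inserted first; random candidates fill the rest.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    pool = MinimaPool(config)
    produced = 0
    for geom in seed_geometries:
        if geom.n != n:
            raise ValueError("seed geometry has wrong water count")
        res = local_minimize(geom, model, config.gtol, config.minimize_max_iter)
        pool.insert(res.geometry, res.energy, 0)
        produced += 1
    while produced < config.population_size:
        geom = random_cluster(n, rng, config.initial_radius_bounds)
        try:
            res = local_minimize(geom, model, config.gtol, config.minimize_max_iter)
        except MinimizationError:
            continue
        pool.insert(res.geometry, res.energy, 0)
        produced += 1
    pool.best_trace.append(pool.best.energy)
    return pool


# ----------------------------------------------------------------------
# variation operators
# ----------------------------------------------------------------------
def _repair(
    ion: np.ndarray,
    waters: list[WaterMolecule],
    max_attempts: int = 100,
) -> list[WaterMolecule]:
    """Resolve overlaps by nudging offending waters radially outward."""
    waters = list(waters)
    for _ in range(max_attempts):
        geom = ClusterGeometry(ion, 2, waters)
        if geom.is_valid():
            return waters
        oxy = geom.oxygen_positions()
        d_ion = np.linalg.norm(oxy - ion, axis=1)
        move = None
        for i in range(len(waters)):
            if d_ion[i] < MIN_ION_O_DISTANCE:
                move = i
                break
        if move is None:
            n = len(waters)
            for i in range(n):
                for j in range(i + 1, n):
                    if np.linalg.norm(oxy[i] - oxy[j]) < MIN_OO_DISTANCE:
                        move = i if d_ion[i] >= d_ion[j] else j
                        break
                if move is not None:
                    break
        if move is None:  # invalid for another reason (non-finite)
            break
        u = oxy[move] - ion
        norm = np.linalg.norm(u)
        u = u / norm if norm > 1e-12 else np.array([0.0, 0.0, 1.0])
        waters[move] = waters[move].translated(0.1 * u)
    raise OperatorFailure("could not repair overlaps by radial nudges")


def crossover_cut_splice(
    parent_a: ClusterGeometry,
    parent_b: ClusterGeometry,
    rng: np.random.Generator,
) -> ClusterGeometry:
    """Cut-and-splice recombination.

    A random plane through the ion splits both parents (working in each
    parent's ion-centered frame).  The child keeps parent A's waters on
    the positive side and fills up to n with parent B's negative-side
    waters nearest the plane (falling back to B's remaining waters if
    that side is short).  Overlaps are repaired by radial nudges; an
    unrepairable child raises :class:`OperatorFailure` and the caller
    retries with a new plane.
    """
    if parent_a.n != parent_b.n:
        raise ValueError("parents must have equal water counts")
    n = parent_a.n
    normal = rng.normal(size=3)
    normal /= np.linalg.norm(normal)

    wa = [w.translated(-parent_a.ion_position) for w in parent_a.waters]
    wb = [w.translated(-parent_b.ion_position) for w in parent_b.waters]
    side_a = [w for w in wa if np.dot(w.oxygen, normal) >= 0.0]
    other_b = sorted(
        (w for w in wb if np.dot(w.oxygen, normal) < 0.0),
        key=lambda w: abs(float(np.dot(w.oxygen, normal))),
    )
    child = side_a + other_b[: n - len(side_a)]
    if len(child) < n:  # B's far side was short: borrow nearest remaining B waters
        rest = sorted(
            (w for w in wb if np.dot(w.oxygen, normal) >= 0.0),
            key=lambda w: abs(float(np.dot(w.oxygen, normal))),
        )
        child += rest[: n - len(child)]
    assert len(child) == n
    repaired = _repair(np.zeros(3), child)
    return ClusterGeometry(np.zeros(3), parent_a.ion_charge, repaired)


def _rotate_water(geom: ClusterGeometry, rng: np.random.Generator) -> ClusterGeometry:
    i = int(rng.integers(geom.n))
    w = geom.waters[i]
    rot = random_rotation_matrix(rng)
    new = WaterMolecule(w.oxygen, (w.hydrogens - w.oxygen) @ rot.T + w.oxygen)
    waters = list(geom.waters)
    waters[i] = new
    return geom.with_waters(waters)


def _shell_hop(geom: ClusterGeometry, rng: np.random.Generator) -> ClusterGeometry:
    i = int(rng.integers(geom.n))
    w = geom.waters[i]
    u = w.oxygen - geom.ion_position
    u /= np.linalg.norm(u)
    delta = rng.uniform(1.5, 2.5) * (1.0 if rng.random() < 0.5 else -1.0)
    # an inward hop that would land inside the ion is reflected outward
    if np.linalg.norm(w.oxygen - geom.ion_position) + delta < MIN_ION_O_DISTANCE:
        delta = abs(delta)
    waters = list(geom.waters)
    waters[i] = w.translated(delta * u)
    return geom.with_waters(waters)


def _twist(geom: ClusterGeometry, rng: np.random.Generator) -> ClusterGeometry:
    d = geom.ion_oxygen_distances()
    radius = rng.uniform(d.min(), d.max()) if geom.n > 1 else d.min() - 0.1
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, 2.0 * np.pi)
    c, s = np.cos(angle), np.sin(angle)
    kx, ky, kz = axis
    kmat = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    rot = np.eye(3) + s * kmat + (1 - c) * (kmat @ kmat)
    waters = []
    for i, w in enumerate(geom.waters):
        if d[i] > radius:
            o = rot @ (w.oxygen - geom.ion_position) + geom.ion_position
            h = (w.hydrogens - geom.ion_position) @ rot.T + geom.ion_position
            waters.append(WaterMolecule(o, h))
        else:
            waters.append(w)
    return geom.with_waters(waters)


_OPERATORS = {"rotate_water": _rotate_water, "shell_hop": _shell_hop, "twist": _twist}


def mutate(
    geometry: ClusterGeometry,
    rng: np.random.Generator,
    weights: Mapping[str, float] | None = None,
) -> ClusterGeometry:
    """Apply exactly one mutation operator chosen by weight.

    Operators: ``rotate_water`` (reorient one water in place),
    ``shell_hop`` (move one water radially by 1.5–2.5 Å), ``twist``
    (rotate all waters beyond a random radius about a random axis).
    The result is overlap-repaired; an unrepairable result raises
    :class:`OperatorFailure`.
    """
    if weights is None:
        weights = {op: 1.0 for op in MUTATION_OPERATORS}
    names = [op for op in MUTATION_OPERATORS if weights.get(op, 0.0) > 0]
    probs = np.array([weights[op] for op in names], dtype=float)
    probs /= probs.sum()
    op = names[int(rng.choice(len(names), p=probs))]
    mutated = _OPERATORS[op](geometry, rng)
    repaired = _repair(mutated.ion_position, list(mutated.waters))
    return mutated.with_waters(repaired)


# ----------------------------------------------------------------------
# deduplication
# ----------------------------------------------------------------------
def is_duplicate(
    a: ClusterGeometry,
    b: ClusterGeometry,
    e_a: float,
    e_b: float,
    config: GAConfig,
) -> bool:
    """Energy + sorted-distance-fingerprint duplicate test.

    Rotation/translation/permutation invariant.  Mirror images share a
    fingerprint (all pair distances are reflection-invariant), so
    enantiomeric minima count as one entry — a documented limitation.
    """
    if a.n != b.n:
        raise ValueError("duplicate test requires equal water counts")
    if abs(e_a - e_b) > config.dedup_energy_tol:
        return False
    ia, oa = a.distance_fingerprint()
    ib, ob = b.distance_fingerprint()
    tol = config.dedup_fingerprint_tol
    return bool(
        np.all(np.abs(ia - ib) <= tol) and np.all(np.abs(oa - ob) <= tol)
    )


# ----------------------------------------------------------------------
# the evolutionary loop
# ----------------------------------------------------------------------
def _tournament(pool: MinimaPool, rng: np.random.Generator) -> PoolEntry:
    i, j = int(rng.integers(len(pool))), int(rng.integers(len(pool)))
    # entries are energy-sorted, so the lower index wins (ties included)
    return pool.entries[min(i, j)]


def evolve(
    n: int,
    model: EnergyModel,
    config: GAConfig,
    seed_geometries: Sequence[ClusterGeometry] = (),
) -> MinimaPool:
    """Run the GA and return the final pool of minima.

    Each generation: tournament-select two parents, cut-and-splice with
    ``crossover_probability`` (else clone), mutate, locally minimize,
    insert if not a duplicate.  Stops at ``max_generations`` or after
    ``stall_generations`` without best-energy improvement beyond
    ``dedup_energy_tol``.  Fully reproducible from ``rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    pool = init_population(n, config, model, rng, seed_geometries)
    best = pool.best.energy
    stall = 0
    for gen in range(1, config.max_generations + 1):
        pa = _tournament(pool, rng)
        pb = _tournament(pool, rng)
        child: ClusterGeometry | None = None
        if rng.random() < config.crossover_probability:
            for _retry in range(20):
                try:
                    child = crossover_cut_splice(pa.geometry, pb.geometry, rng)
                    break
                except OperatorFailure:
                    continue
        if child is None:
            child = pa.geometry
        try:
            child = mutate(child, rng, config.mutation_weights)
            res = local_minimize(child, model, config.gtol, config.minimize_max_iter)
        except (OperatorFailure, MinimizationError, InvalidGeometryError) as exc:
            logger.warning("generation %d: offspring skipped (%s)", gen, exc)
            pool.best_trace.append(pool.best.energy)
            continue
        if res.geometry.is_valid():
            pool.insert(res.geometry, res.energy, gen)
        pool.best_trace.append(pool.best.energy)
        if best - pool.best.energy > config.dedup_energy_tol:
            best = pool.best.energy
            stall = 0
        else:
            stall += 1
            if stall >= config.stall_generations:
                break
    return pool
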