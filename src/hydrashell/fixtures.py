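"""Synthetic cluster fixtures with planted ground truth, and brute-force oracles.

The generator builds ion–water clusters whose hydration-shell labels
and hydrogen-bond topology are known *by construction*: a first shell
of ion-oriented waters (dipoles pointing away from the cation, so they
cannot donate to each other), outer-shell waters positioned so each
planted donor→acceptor bond satisfies the default geometric criterion
with a safety margin, and optional positional jitter that is rejected
whenever it would break (or add to) the planted relations.  These
structures are analysis-stage ground truth only — they are not claimed
to be minima of any potential.

``multistart_oracle`` is the independent global-minimum oracle used to
validate the GA: best of many independent random-placement local
minimizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import ClusterGeometry, WaterMolecule
from .ga import random_cluster
from .potential import EnergyModel, MinimizationError, local_minimize
from .shells import (
    FIRST_SHELL_CUTOFF,
    HBond,
    HBondCriterion,
    HBondGraph,
    ShellAssignment,
    assign_shells,
    detect_hbonds,
    first_shell_hbond_count,
)

__all__ = [
    "FixtureSpec",
    "FixtureInfeasibleError",
    "build_fixture",
    "random_feasible_spec",
    "multistart_oracle",
]

_THETA0 = np.deg2rad(109.47)
_R_OH = 1.0


class FixtureInfeasibleError(RuntimeError):
    """The requested planted topology cannot be realised without overlap."""


@dataclass(frozen=True)
class FixtureSpec:
    """Planted shell populations and H-bond topology.

    Waters are indexed shell-by-shell: 0..N1-1 first shell, then N2
    second-shell, then N3 third-shell waters.  ``hbond_edges`` are
    (donor, acceptor) pairs in those indices; every outer-shell water
    must accept exactly one planted bond from the shell below it, and a
    donor can use at most its two hydrogens.
    """

    n1: int
    n2: int = 0
    n3: int = 0
    hbond_edges: tuple[tuple[int, int], ...] = ()
    shell_radii: tuple[float, float, float] = (2.40, 4.30, 5.60)
    oo_distance: float = 2.80   # target O–O along planted bonds (Å)
    jitter: float = 0.05        # Å
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "hbond_edges", tuple(map(tuple, self.hbond_edges)))
        if self.n1 < 1 or self.n2 < 0 or self.n3 < 0:
            raise ValueError("shell counts must be n1 >= 1, n2, n3 >= 0")
        r1, r2, r3 = self.shell_radii
        if not (0 < r1 < r2 < r3):
            raise ValueError("shell radii must be strictly increasing")
        n = self.n
        shell = self.planted_shell_index()
        donated: dict[int, int] = {}
        incoming = {i: 0 for i in range(self.n1, n)}
        for d, a in self.hbond_edges:
            if not (0 <= d < n and 0 <= a < n) or d == a:
                raise ValueError(f"bad edge ({d}, {a})")
            if shell[a] != shell[d] + 1:
                raise ValueError(
                    "each planted bond must connect shell k to shell k+1"
                )
            donated[d] = donated.get(d, 0) + 1
            if donated[d] > 2:
                raise ValueError(f"water {d} would donate more than two bonds")
            incoming[a] += 1
        for a, cnt in incoming.items():
            if cnt != 1:
                raise ValueError(
                    f"outer water {a} must accept exactly one planted bond"
                )

    @property
    def n(self) -> int:
        return self.n1 + self.n2 + self.n3

    def planted_shell_index(self) -> tuple[int, ...]:
        return (1,) * self.n1 + (2,) * self.n2 + (3,) * self.n3


def _relaxed_directions(k: int, rng: np.random.Generator) -> np.ndarray:
    """k unit vectors spread by repulsion relaxation on the sphere.

    Electrostatically natural packing (octahedral-like at k=6) that
    stays constructible for any k, unlike fixed polyhedra.
    """
    u = rng.normal(size=(k, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    if k == 1:
        return u
    for _ in range(400):
        force = np.zeros_like(u)
        for i in range(k):
            diff = u[i] - u
            d3 = (np.linalg.norm(diff, axis=1) ** 3)[:, None]
            d3[i] = np.inf
            force[i] = (diff / d3).sum(axis=0)
        # project onto the tangent plane and take a damped step
        force -= (force * u).sum(axis=1, keepdims=True) * u
        u += 0.05 * force
        u /= np.linalg.norm(u, axis=1, keepdims=True)
    return u


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    kx, ky, kz = axis
    kmat = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + s * kmat + (1 - c) * (kmat @ kmat)


def _perp(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    v -= np.dot(v, u) * u
    n = np.linalg.norm(v)
    if n < 1e-8:
        return _perp(u, rng)
    return v / n


def _water_from_dirs(oxygen: np.ndarray, h_dirs: np.ndarray) -> WaterMolecule:
    return WaterMolecule(oxygen, oxygen + _R_OH * h_dirs)


def _bisector_water(oxygen: np.ndarray, bisector: np.ndarray,
                    rng: np.random.Generator) -> WaterMolecule:
    """Water with its H–O–H bisector along ``bisector`` (dipole direction)."""
    b = bisector / np.linalg.norm(bisector)
    p = _perp(b, rng)
    half = _THETA0 / 2.0
    h1 = np.cos(half) * b + np.sin(half) * p
    h2 = np.cos(half) * b - np.sin(half) * p
    return _water_from_dirs(oxygen, np.array([h1, h2]))


def _build_once(spec: FixtureSpec, rng: np.random.Generator):
    r_shell = {1: spec.shell_radii[0], 2: spec.shell_radii[1], 3: spec.shell_radii[2]}
    shell = spec.planted_shell_index()
    n = spec.n
    positions = np.full((n, 3), np.nan)
    dirs1 = _relaxed_directions(spec.n1, rng)
    positions[: spec.n1] = r_shell[1] * dirs1

    incoming = {a: d for d, a in spec.hbond_edges}
    # place outer waters shell by shell so donors exist before acceptors
    for idx in range(spec.n1, n):
        d = incoming[idx]
        rd = np.linalg.norm(positions[d])
        rk = r_shell[shell[idx]]
        # law of cosines: angular offset from the donor direction so that
        # the acceptor sits on its shell at the target O-O separation
        d_oo = spec.oo_distance
        cosg = (rd * rd + rk * rk - d_oo * d_oo) / (2 * rd * rk)
        if abs(cosg) > 1.0:
            raise FixtureInfeasibleError(
                "shell radii and O-O target are geometrically inconsistent"
            )
        gamma = float(np.arccos(cosg))
        u_d = positions[d] / rd
        t0 = _perp(u_d, rng)
        best = None
        placed = positions[~np.isnan(positions[:, 0])]
        phi0 = rng.uniform(0, 2 * np.pi)
        for k in range(24):
            t = _rotation_about(u_d, phi0 + 2 * np.pi * k / 24.0) @ t0
            cand = rk * (np.cos(gamma) * u_d + np.sin(gamma) * t)
            dmin = np.min(np.linalg.norm(placed - cand, axis=1)) if len(placed) else np.inf
            if best is None or dmin > best[0]:
                best = (dmin, cand)
        if best is None or best[0] < 2.2:
            raise FixtureInfeasibleError("cannot place outer water without overlap")
        positions[idx] = best[1]

    # orient: donors point an H at each of their acceptors; spare
    # hydrogens (and non-donors) point away from the ion
    donated: dict[int, list[int]] = {}
    for d, a in spec.hbond_edges:
        donated.setdefault(d, []).append(a)
    waters: list[WaterMolecule] = []
    edges: list[HBond] = []
    for i in range(n):
        radial = positions[i] / np.linalg.norm(positions[i])
        accs = donated.get(i, [])
        if not accs:
            waters.append(_bisector_water(positions[i], radial, rng))
            continue
        h_dirs = []
        for a in accs:
            v = positions[a] - positions[i]
            h_dirs.append(v / np.linalg.norm(v))
        if len(h_dirs) == 1:
            # second H in the (bond, radial) plane, tilted outward
            h1 = h_dirs[0]
            w = radial - np.dot(radial, h1) * h1
            nw = np.linalg.norm(w)
            w = w / nw if nw > 1e-8 else _perp(h1, rng)
            h_dirs.append(np.cos(_THETA0) * h1 + np.sin(_THETA0) * w)
        waters.append(_water_from_dirs(positions[i], np.array(h_dirs[:2])))
        for k, a in enumerate(accs):
            edges.append(HBond(i, a, k))
    geometry = ClusterGeometry(np.zeros(3), 2, waters)
    planted_shells = ShellAssignment(shell)
    planted_graph = HBondGraph(tuple(edges))
    return geometry, planted_shells, planted_graph


def _recovers(
    geometry: ClusterGeometry,
    planted_shells: ShellAssignment,
    planted_graph: HBondGraph,
    criterion: HBondCriterion,
) -> bool:
    if not geometry.is_valid():
        return False
    hb = detect_hbonds(geometry, criterion)
    if hb.edge_set() != planted_graph.edge_set():
        return False
    sh = assign_shells(geometry, hb, FIRST_SHELL_CUTOFF)
    if sh.shell_index != planted_shells.shell_index or sh.fallback or sh.unassigned:
        return False
    return first_shell_hbond_count(sh, hb) == 0


def _margins_ok(
    geometry: ClusterGeometry,
    planted_graph: HBondGraph,
    criterion: HBondCriterion,
) -> bool:
    """Planted bonds must pass the criterion with >= 0.2 Å / 10° to spare."""
    tight = HBondCriterion(
        max_OO_distance=criterion.max_OO_distance - 0.2,
        min_OHO_angle=criterion.min_OHO_angle + 10.0,
        max_HO_distance=criterion.max_HO_distance - 0.2,
    )
    hb = detect_hbonds(geometry, tight)
    return planted_graph.edge_set() <= hb.edge_set()


def build_fixture(
    spec: FixtureSpec,
    criterion: HBondCriterion = HBondCriterion(),
) -> tuple[ClusterGeometry, ShellAssignment, HBondGraph]:
    """Build a cluster realising the planted truth of ``spec``.

    Returns (geometry, planted shell assignment, planted H-bond graph);
    the default analysis recovers both exactly, including after the
    jitter (which is rejection-sampled so no planted relation breaks
    and no spurious one appears).  Raises
    :class:`FixtureInfeasibleError` when the topology cannot be packed.
    """
    rng = np.random.default_rng(spec.rng_seed)
    base = None
    for _attempt in range(20):
        try:
            geometry, shells, graph = _build_once(spec, rng)
        except FixtureInfeasibleError:
            continue
        if _recovers(geometry, shells, graph, criterion) and _margins_ok(
            geometry, graph, criterion
        ):
            base = (geometry, shells, graph)
            break
    if base is None:
        raise FixtureInfeasibleError(
            f"could not realise planted topology {spec!r}"
        )
    geometry, shells, graph = base
    if spec.jitter <= 0:
        return geometry, shells, graph
    coords = geometry.coordinates()
    for _attempt in range(50):
        noisy = coords + rng.normal(scale=spec.jitter, size=coords.shape)
        cand = ClusterGeometry.from_coordinates(noisy, geometry.ion_charge)
        if _recovers(cand, shells, graph, criterion):
            return cand, shells, graph
    raise FixtureInfeasibleError(
        "jitter rejection failed 50 times; lower the jitter amplitude"
    )


def random_feasible_spec(rng: np.random.Generator, jitter: float = 0.05) -> FixtureSpec:
    """Draw a random planted topology within the motifs the analysis targets.

    First shells of 4–8 waters, second shells attached by one H-bond
    each to first-shell donors (at most two per donor), and up to two
    third-shell waters chained onto distinct second-shell donors.
    """
    n1 = int(rng.integers(4, 9))
    n2 = int(rng.integers(0, min(2 * n1, 8) + 1))
    n3 = int(rng.integers(0, min(n2, 2) + 1))
    edges = []
    capacity = {i: 2 for i in range(n1)}
    for a in range(n1, n1 + n2):
        donors = [d for d, c in capacity.items() if c > 0]
        d = int(rng.choice(donors))
        capacity[d] -= 1
        edges.append((d, a))
    cap2 = {i: 2 for i in range(n1, n1 + n2)}
    for a in range(n1 + n2, n1 + n2 + n3):
        donors = [d for d, c in cap2.items() if c > 0]
        d = int(rng.choice(donors))
        cap2[d] -= 1
        edges.append((d, a))
    return FixtureSpec(
        n1=n1,
        n2=n2,
        n3=n3,
        hbond_edges=tuple(edges),
        jitter=jitter,
        rng_seed=int(rng.integers(2**31)),
    )


def multistart_oracle(
    n: int,
    model: EnergyModel,
    restarts: int,
    rng_seed: int = 0,
    radius_bounds: tuple[float, float] = (2.2, 5.5),
    gtol: float = 1e-4,
) -> tuple[ClusterGeometry, float]:
    """Best of ``restarts`` independent random-placement minimizations.

    The brute-force stand-in for global search at small n; deterministic
    under ``rng_seed``.  Minimization failures are skipped (counted
    against the restart budget).
    """
    rng = np.random.default_rng(rng_seed)
    best: tuple[ClusterGeometry, float] | None = None
    for _ in range(restarts):
        geom = random_cluster(n, rng, radius_bounds)
        try:
            res = local_minimize(geom, model, gtol)
        except MinimizationError:
            continue
        if best is None or res.energy < best[1]:
            best = (res.geometry, res.energy)
    if best is None:
        raise RuntimeError("all restarts failed to minimize")
    return best
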