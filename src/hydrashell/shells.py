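"""Structural observables of hydrated-ion clusters.

Hydrogen-bond detection (geometric distance/angle criterion), hydration
shell assignment (first shell by ion–O distance, outer shells by
hydrogen-bond graph distance), and the summary distances reported for
such clusters: mean H-bonded O–O separation and mean ion–O distance per
shell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .geometry import ClusterGeometry

__all__ = [
    "HBondCriterion",
    "HBond",
    "HBondGraph",
    "ShellAssignment",
    "ShellDistanceReport",
    "detect_hbonds",
    "assign_shells",
    "shell_distances",
    "first_shell_hbond_count",
    "shell_series",
    "FIRST_SHELL_CUTOFF",
    "SHELL2_FALLBACK_CUTOFF",
    "SHELL3_FALLBACK_CUTOFF",
]

FIRST_SHELL_CUTOFF = 3.2        # Å; midpoint of the gap between shells 1 and 2
SHELL2_FALLBACK_CUTOFF = 5.0    # Å; distance bins used only for waters
SHELL3_FALLBACK_CUTOFF = 7.0    # Å; unreachable through the H-bond graph


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond criterion O_d–H···O_a.

    A donor H forms a bond to an acceptor O when the O–O distance, the
    H···O distance and the O–H···O angle all pass.  Defaults follow
    common practice for water (3.5 Å / 140° / 2.6 Å); the source data
    this package emulates marks H-bonds graphically without stating a
    numeric rule, so all three are configurable.
    """

    max_OO_distance: float = 3.5   # Å
    min_OHO_angle: float = 140.0   # degrees
    max_HO_distance: float = 2.6   # Å

    def __post_init__(self) -> None:
        if min(self.max_OO_distance, self.min_OHO_angle, self.max_HO_distance) <= 0:
            raise ValueError("criterion values must be positive")
        if self.min_OHO_angle > 180.0:
            raise ValueError("angle cannot exceed 180 degrees")


@dataclass(frozen=True)
class HBond:
    donor: int      # water index providing the H
    acceptor: int   # water index providing the lone-pair O
    h_index: int    # 0 or 1: which H of the donor


@dataclass(frozen=True)
class HBondGraph:
    """Directed donor→acceptor hydrogen-bond edges of one cluster."""

    edges: tuple[HBond, ...]

    @property
    def n_hb(self) -> int:
        return len(self.edges)

    def undirected(self, n_waters: int) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(n_waters))
        g.add_edges_from((e.donor, e.acceptor) for e in self.edges)
        return g

    def edge_set(self) -> set[tuple[int, int]]:
        return {(e.donor, e.acceptor) for e in self.edges}


@dataclass(frozen=True)
class ShellAssignment:
    """Per-water hydration-shell labels and the shell populations.

    ``shell_index[i]`` is 1 for waters directly coordinating the ion,
    2/3 for outer shells; waters beyond shell 3 carry their raw index
    but are listed in ``unassigned``.  ``fallback`` flags waters binned
    by raw distance because no H-bond path connects them to shell 1.
    """

    shell_index: tuple[int, ...]
    unassigned: tuple[int, ...] = ()
    fallback: tuple[int, ...] = ()

    @property
    def n1(self) -> int:
        return self._count(1)

    @property
    def n2(self) -> int:
        return self._count(2)

    @property
    def n3(self) -> int:
        return self._count(3)

    def _count(self, k: int) -> int:
        una = set(self.unassigned)
        return sum(
            1 for i, s in enumerate(self.shell_index) if s == k and i not in una
        )

    def waters_in_shell(self, k: int) -> list[int]:
        una = set(self.unassigned)
        return [i for i, s in enumerate(self.shell_index) if s == k and i not in una]


@dataclass(frozen=True)
class ShellDistanceReport:
    """Mean structural distances (Å); ``None`` where a shell is empty."""

    mean_OO_hbonded: float | None
    mean_CaO_shell1: float | None
    mean_CaO_shell2: float | None
    mean_CaO_shell3: float | None


def detect_hbonds(
    geometry: ClusterGeometry, criterion: HBondCriterion = HBondCriterion()
) -> HBondGraph:
    """Find all donor→acceptor hydrogen bonds between waters.

    If both hydrogens of a donor qualify toward the same acceptor only
    the larger-angle one is kept, so a (donor, H) pair donates at most
    one bond per acceptor and N_HB counts distinct donor→acceptor links.
    """
    geometry.validate()
    n = geometry.n
    oxy = geometry.oxygen_positions()
    edges: list[HBond] = []
    for d in range(n):
        for a in range(n):
            if d == a:
                continue
            d_oo = float(np.linalg.norm(oxy[d] - oxy[a]))
            if d_oo > criterion.max_OO_distance:
                continue
            best: tuple[float, int] | None = None
            for h in range(2):
                h_pos = geometry.waters[d].hydrogens[h]
                d_ho = float(np.linalg.norm(h_pos - oxy[a]))
                if d_ho > criterion.max_HO_distance:
                    continue
                u = oxy[d] - h_pos
                v = oxy[a] - h_pos
                cosang = float(
                    np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                )
                ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if ang < criterion.min_OHO_angle:
                    continue
                if best is None or ang > best[0]:
                    best = (ang, h)
            if best is not None:
                edges.append(HBond(d, a, best[1]))
    return HBondGraph(tuple(edges))


def assign_shells(
    geometry: ClusterGeometry,
    hbonds: HBondGraph,
    first_shell_cutoff: float = FIRST_SHELL_CUTOFF,
) -> ShellAssignment:
    """Label each water with its hydration shell.

    Shell 1: ion–O distance within ``first_shell_cutoff``.  Shell k>1:
    waters at undirected H-bond graph distance k−1 from the nearest
    shell-1 water.  Waters with no H-bond path to the first shell fall
    back to raw distance bins (flagged in ``fallback``); waters beyond
    shell 3 land in ``unassigned``.
    """
    geometry.validate()
    n = geometry.n
    d_ion = geometry.ion_oxygen_distances()
    first = [i for i in range(n) if d_ion[i] <= first_shell_cutoff]
    shell = [0] * n
    fallback: list[int] = []
    unassigned: list[int] = []
    if not first:
        if n:
            warnings.warn(
                "degenerate structure: no first-shell water; using distance bins",
                stacklevel=2,
            )
        for i in range(n):
            fallback.append(i)
            shell[i] = _distance_bin(d_ion[i])
            if shell[i] == 0:
                unassigned.append(i)
        return ShellAssignment(tuple(shell), tuple(unassigned), tuple(fallback))

    g = hbonds.undirected(n)
    dist = nx.multi_source_dijkstra_path_length(g, set(first)) if first else {}
    for i in range(n):
        if i in set(first):
            shell[i] = 1
            continue
        if i in dist:
            k = 1 + int(dist[i])
            shell[i] = k
            if k > 3:
                unassigned.append(i)
        else:
            fallback.append(i)
            shell[i] = _distance_bin(d_ion[i])
            if shell[i] == 0:
                unassigned.append(i)
    return ShellAssignment(tuple(shell), tuple(unassigned), tuple(fallback))


def _distance_bin(d: float) -> int:
    if d <= SHELL2_FALLBACK_CUTOFF:
        return 2
    if d <= SHELL3_FALLBACK_CUTOFF:
        return 3
    return 0  # unassigned


def shell_distances(
    geometry: ClusterGeometry,
    shells: ShellAssignment,
    hbonds: HBondGraph,
) -> ShellDistanceReport:
    """Arithmetic-mean distances over H-bonded O–O pairs and per shell."""
    oxy = geometry.oxygen_positions()
    d_ion = geometry.ion_oxygen_distances()
    pairs = {tuple(sorted((e.donor, e.acceptor))) for e in hbonds.edges}
    mean_oo = (
        float(np.mean([np.linalg.norm(oxy[i] - oxy[j]) for i, j in pairs]))
        if pairs
        else None
    )
    means = []
    for k in (1, 2, 3):
        idx = shells.waters_in_shell(k)
        means.append(float(np.mean(d_ion[idx])) if idx else None)
    return ShellDistanceReport(mean_oo, *means)


def first_shell_hbond_count(shells: ShellAssignment, hbonds: HBondGraph) -> int:
    """Number of H-bond edges with both endpoints in the first shell."""
    first = set(shells.waters_in_shell(1))
    return sum(1 for e in hbonds.edges if e.donor in first and e.acceptor in first)


def shell_series(
    geometries: Mapping[int, ClusterGeometry],
    criterion: HBondCriterion = HBondCriterion(),
    first_shell_cutoff: float = FIRST_SHELL_CUTOFF,
) -> pd.DataFrame:
    """Tabulate shell/H-bond observables over a size series.

    One row per cluster size n, sorted by n, with columns
    ``n, N1, N2, N3, N_HB, mean_OO, mean_CaO1, mean_CaO2, mean_CaO3``.
    """
    rows = []
    for n in sorted(geometries):
        geom = geometries[n]
        if geom.n != n:
            warnings.warn(f"geometry for n={n} has {geom.n} waters; row omitted")
            continue
        hb = detect_hbonds(geom, criterion)
        sh = assign_shells(geom, hb, first_shell_cutoff)
        rep = shell_distances(geom, sh, hb)
        rows.append(
            {
                "n": n,
                "N1": sh.n1,
                "N2": sh.n2,
                "N3": sh.n3,
                "N_HB": hb.n_hb,
                "mean_OO": rep.mean_OO_hbonded,
                "mean_CaO1": rep.mean_CaO_shell1,
                "mean_CaO2": rep.mean_CaO_shell2,
                "mean_CaO3": rep.mean_CaO_shell3,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["n", "N1", "N2", "N3", "N_HB", "mean_OO", "mean_CaO1", "mean_CaO2", "mean_CaO3"],
    )
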