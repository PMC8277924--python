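"""Cluster geometries: one metal ion plus n water molecules in Cartesian space.

The package works on finite ion–water clusters M^q+(H2O)_n.  A
:class:`ClusterGeometry` is the object that is searched (GA), relaxed
(local minimization), analyzed (shells, hydrogen bonds) and serialized
(XYZ).  All coordinates are in Ångström throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "WaterMolecule",
    "ClusterGeometry",
    "InvalidGeometryError",
    "MIN_OO_DISTANCE",
    "MIN_ION_O_DISTANCE",
]

# Validity gates for generated / parsed structures (Å).
MIN_OO_DISTANCE = 1.8
MIN_ION_O_DISTANCE = 1.5


class InvalidGeometryError(ValueError):
    """Raised when a structure violates the cluster validity gates."""


@dataclass(frozen=True)
class WaterMolecule:
    """One water molecule: oxygen plus two hydrogens (Å)."""

    oxygen: np.ndarray
    hydrogens: np.ndarray  # shape (2, 3)

    def __post_init__(self) -> None:
        object.__setattr__(self, "oxygen", np.asarray(self.oxygen, dtype=float))
        object.__setattr__(self, "hydrogens", np.asarray(self.hydrogens, dtype=float))
        if self.oxygen.shape != (3,) or self.hydrogens.shape != (2, 3):
            raise ValueError("water molecule needs one O (3,) and two H (2, 3)")

    @property
    def oh_distances(self) -> np.ndarray:
        return np.linalg.norm(self.hydrogens - self.oxygen, axis=1)

    @property
    def hoh_angle(self) -> float:
        """H–O–H angle in degrees."""
        u = self.hydrogens[0] - self.oxygen
        v = self.hydrogens[1] - self.oxygen
        c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def translated(self, shift: np.ndarray) -> "WaterMolecule":
        return WaterMolecule(self.oxygen + shift, self.hydrogens + shift)


@dataclass(frozen=True)
class ClusterGeometry:
    """An ion plus an ordered list of water molecules.

    Parameters
    ----------
    ion_position
        Cartesian position of the ion (Å).
    ion_charge
        Integer charge in elementary units (+2 for Ca²⁺).
    waters
        Ordered water molecules.  Water order is meaningful only as an
        index: every observable computed from a geometry is invariant
        under permuting it.
    """

    ion_position: np.ndarray
    ion_charge: int = 2
    waters: tuple[WaterMolecule, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ion_position", np.asarray(self.ion_position, dtype=float))
        object.__setattr__(self, "waters", tuple(self.waters))
        if self.ion_position.shape != (3,):
            raise ValueError("ion_position must be a 3-vector")

    @property
    def n(self) -> int:
        """Number of water molecules."""
        return len(self.waters)

    @property
    def n_atoms(self) -> int:
        return 1 + 3 * self.n

    # ------------------------------------------------------------------
    # flat-coordinate view used by the numeric kernels: ion, then O,H,H
    # per water, row-major (n_atoms, 3)
    # ------------------------------------------------------------------
    def coordinates(self) -> np.ndarray:
        coords = np.empty((self.n_atoms, 3), dtype=float)
        coords[0] = self.ion_position
        for i, w in enumerate(self.waters):
            coords[1 + 3 * i] = w.oxygen
            coords[2 + 3 * i] = w.hydrogens[0]
            coords[3 + 3 * i] = w.hydrogens[1]
        return coords

    @classmethod
    def from_coordinates(
        cls, coords: np.ndarray, ion_charge: int = 2
    ) -> "ClusterGeometry":
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or (coords.shape[0] - 1) % 3 != 0:
            raise ValueError("coordinate array must be (1 + 3n, 3)")
        n = (coords.shape[0] - 1) // 3
        waters = tuple(
            WaterMolecule(coords[1 + 3 * i], coords[2 + 3 * i : 4 + 3 * i])
            for i in range(n)
        )
        return cls(coords[0], ion_charge, waters)

    def oxygen_positions(self) -> np.ndarray:
        """(n, 3) array of water-oxygen positions."""
        if self.n == 0:
            return np.empty((0, 3))
        return np.stack([w.oxygen for w in self.waters])

    def ion_oxygen_distances(self) -> np.ndarray:
        """Distance of each water oxygen from the ion (Å)."""
        if self.n == 0:
            return np.empty(0)
        return np.linalg.norm(self.oxygen_positions() - self.ion_position, axis=1)

    # ------------------------------------------------------------------
    # validity
    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`InvalidGeometryError` on gate violations."""
        coords = self.coordinates()
        if not np.all(np.isfinite(coords)):
            raise InvalidGeometryError("non-finite coordinates")
        oxy = self.oxygen_positions()
        if self.n:
            d_ion = np.linalg.norm(oxy - self.ion_position, axis=1)
            if np.any(d_ion < MIN_ION_O_DISTANCE):
                raise InvalidGeometryError(
                    f"oxygen closer than {MIN_ION_O_DISTANCE} Å to the ion"
                )
        if self.n > 1:
            diff = oxy[:, None, :] - oxy[None, :, :]
            d = np.linalg.norm(diff, axis=-1)
            iu = np.triu_indices(self.n, k=1)
            if np.any(d[iu] < MIN_OO_DISTANCE):
                raise InvalidGeometryError(
                    f"two oxygens closer than {MIN_OO_DISTANCE} Å"
                )

    def is_valid(self) -> bool:
        try:
            self.validate()
        except InvalidGeometryError:
            return False
        return True

    # ------------------------------------------------------------------
    # transforms
    # ------------------------------------------------------------------
    def translated(self, shift: Sequence[float]) -> "ClusterGeometry":
        shift = np.asarray(shift, dtype=float)
        return ClusterGeometry(
            self.ion_position + shift,
            self.ion_charge,
            tuple(w.translated(shift) for w in self.waters),
        )

    def rotated(self, rotation: np.ndarray, center: Sequence[float] | None = None) -> "ClusterGeometry":
        """Rigidly rotate by a 3×3 rotation matrix about ``center`` (default: ion)."""
        rotation = np.asarray(rotation, dtype=float)
        c = self.ion_position if center is None else np.asarray(center, dtype=float)
        coords = (self.coordinates() - c) @ rotation.T + c
        return ClusterGeometry.from_coordinates(coords, self.ion_charge)

    def permuted(self, order: Iterable[int]) -> "ClusterGeometry":
        order = list(order)
        if sorted(order) != list(range(self.n)):
            raise ValueError("order must be a permutation of the water indices")
        return replace(self, waters=tuple(self.waters[i] for i in order))

    def with_waters(self, waters: Iterable[WaterMolecule]) -> "ClusterGeometry":
        return replace(self, waters=tuple(waters))

    # ------------------------------------------------------------------
    # rotation/translation/permutation-invariant fingerprint
    # ------------------------------------------------------------------
    def distance_fingerprint(self) -> tuple[np.ndarray, np.ndarray]:
        """Sorted ion–O distances and sorted O–O distances.

        Invariant under rigid motion and water reindexing (and, as a
        documented limitation, under reflection: mirror images share a
        fingerprint).
        """
        oxy = self.oxygen_positions()
        d_ion = np.sort(np.linalg.norm(oxy - self.ion_position, axis=1))
        if self.n > 1:
            iu = np.triu_indices(self.n, k=1)
            d_oo = np.sort(
                np.linalg.norm(oxy[iu[0]] - oxy[iu[1]], axis=1)
            )
        else:
            d_oo = np.empty(0)
        return d_ion, d_oo


def random_rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation (Haar measure) via quaternions."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
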