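"""Empirical ion–water potential: energy, analytic gradient, local minimization.

The potential is the desk-scale stand-in for a quantum-chemical surface:
a 3-site flexible water (SPC-like charges, stiff harmonic O–H / H–O–H
restraints) interacting with a bare dication through Coulomb plus an
ion–O Lennard-Jones term.  Energies are kJ/mol, lengths Å, charges e.

The backend contract any higher-fidelity engine must honour is simply:
``energy(geometry) -> kJ/mol`` and ``gradient(geometry) -> (n_atoms, 3)``
consistent with it; everything downstream (GA search, thermochemistry)
uses only these two callables plus fragment energies for the
counterpoise bookkeeping.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from . import _kernels as K
from .geometry import ClusterGeometry, InvalidGeometryError

__all__ = [
    "EnergyModel",
    "REFERENCE_MODEL",
    "SingularityError",
    "MinimizationError",
    "MinimizationResult",
    "energy",
    "gradient",
    "local_minimize",
]


class SingularityError(ValueError):
    """Two interaction sites closer than 1e-6 Å."""


class MinimizationError(RuntimeError):
    """Minimization diverged to a non-finite energy.

    Carries the last valid iterate in ``last_geometry``.
    """

    def __init__(self, message: str, last_geometry: ClusterGeometry | None = None):
        super().__init__(message)
        self.last_geometry = last_geometry


@dataclass(frozen=True)
class EnergyModel:
    """Parameter set of the site–site potential.

    Defaults are the shipped reference model: SPC charges and O–O
    dispersion, stiff intramolecular restraints, and an ion–O
    Lennard-Jones sigma calibrated so the minimized Ca²⁺(H₂O)₁ complex
    sits in the experimental/first-principles first-shell window
    (Ca–O ≈ 2.4 Å).
    """

    q_O: float = -0.8476
    q_H: float = 0.4238
    q_ion: float = 2.0
    eps_OO: float = 0.6502       # kJ/mol
    sigma_OO: float = 3.166      # Å
    eps_ion_O: float = 0.6502    # kJ/mol
    sigma_ion_O: float = 3.037   # Å, calibrated (see docs/methods.md)
    k_bond: float = 4000.0       # kJ/mol/Å^2
    r0: float = 1.0              # Å
    k_angle: float = 400.0       # kJ/mol/rad^2
    theta0: float = np.deg2rad(109.47)  # rad
    k_e: float = 1389.35         # kJ mol^-1 Å e^-2

    def __post_init__(self) -> None:
        if abs(self.q_O + 2 * self.q_H) > 1e-9:
            raise ValueError("water must be neutral: q_O + 2 q_H == 0")
        for name in ("eps_OO", "eps_ion_O", "k_bond", "k_angle"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("sigma_OO", "sigma_ion_O"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def param_vector(self) -> np.ndarray:
        p = np.empty(K.N_PARAMS)
        p[K.PARAM_Q_O] = self.q_O
        p[K.PARAM_Q_H] = self.q_H
        p[K.PARAM_Q_ION] = self.q_ion
        p[K.PARAM_EPS_OO] = self.eps_OO
        p[K.PARAM_SIG_OO] = self.sigma_OO
        p[K.PARAM_EPS_ION_O] = self.eps_ion_O
        p[K.PARAM_SIG_ION_O] = self.sigma_ion_O
        p[K.PARAM_K_BOND] = self.k_bond
        p[K.PARAM_R0] = self.r0
        p[K.PARAM_K_ANGLE] = self.k_angle
        p[K.PARAM_THETA0] = self.theta0
        p[K.PARAM_KE] = self.k_e
        return p

    def without_ion_interactions(self) -> "EnergyModel":
        """Copy with the ion decoupled (q_ion = 0, no ion–O LJ).

        Used to evaluate E[(H2O)_n] at the frozen cluster geometry for
        the per-ligand interaction energy.
        """
        return dataclasses.replace(self, q_ion=0.0, eps_ion_O=0.0)

    # --- YAML plumbing -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["theta0_deg"] = float(np.rad2deg(d.pop("theta0")))
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "EnergyModel":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)} | {"theta0_deg"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown model keys: {sorted(unknown)}")
        if "theta0_deg" in data:
            data["theta0"] = float(np.deg2rad(data.pop("theta0_deg")))
        return cls(**data)


#: Shipped reference parameter set (see :class:`EnergyModel` defaults).
REFERENCE_MODEL = EnergyModel()


@dataclass(frozen=True)
class MinimizationResult:
    geometry: ClusterGeometry
    energy: float
    n_iter: int
    converged: bool


def _check(geometry: ClusterGeometry) -> None:
    if not np.all(np.isfinite(geometry.coordinates())):
        raise InvalidGeometryError("non-finite coordinates")


def energy(geometry: ClusterGeometry, model: EnergyModel = REFERENCE_MODEL) -> float:
    """Total potential energy of a cluster (kJ/mol)."""
    _check(geometry)
    e, _, status = K.energy_gradient(
        geometry.coordinates().ravel(), model.param_vector(), geometry.n
    )
    if status == K.STATUS_SINGULAR:
        raise SingularityError("overlapping interaction sites (r < 1e-6 Å)")
    return float(e)


def gradient(geometry: ClusterGeometry, model: EnergyModel = REFERENCE_MODEL) -> np.ndarray:
    """Analytic energy gradient, shape (n_atoms, 3), kJ/mol/Å."""
    _check(geometry)
    _, g, status = K.energy_gradient(
        geometry.coordinates().ravel(), model.param_vector(), geometry.n
    )
    if status == K.STATUS_SINGULAR:
        raise SingularityError("overlapping interaction sites (r < 1e-6 Å)")
    return g.reshape(-1, 3)


def local_minimize(
    geometry: ClusterGeometry,
    model: EnergyModel = REFERENCE_MODEL,
    gtol: float = 1e-4,
    max_iter: int = 2000,
) -> MinimizationResult:
    """Relax a cluster to a nearby local minimum (quasi-Newton L-BFGS).

    ``gtol`` is the max-norm gradient threshold in kJ/mol/Å.  On hitting
    the iteration cap the best iterate is returned with
    ``converged=False``.
    """
    _check(geometry)
    x0 = geometry.coordinates().ravel()
    x, f, n_iter, converged = K.minimize_cluster(
        x0, model.param_vector(), geometry.n, gtol, max_iter
    )
    if not np.isfinite(f):
        raise MinimizationError(
            "minimization diverged to non-finite energy",
            last_geometry=ClusterGeometry.from_coordinates(
                x.reshape(-1, 3), geometry.ion_charge
            ),
        )
    out = ClusterGeometry.from_coordinates(x.reshape(-1, 3), geometry.ion_charge)
    return MinimizationResult(out, float(f), int(n_iter), bool(converged))
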