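"""Energy bookkeeping and harmonic (RRHO) thermochemistry.

Three exact-arithmetic observables used to characterise ion–water
clusters:

* counterpoise BSSE, ``ΔE_BSSE = Σ_i [E_i^full − E_i^frag]`` over the m
  fragments of a cluster (identically zero for a basis-free empirical
  backend — the operation is bookkeeping over supplied fragment
  energies);
* sequential water binding energy,
  ``ΔE_seq = E(H2O) + E[M(H2O)_{n−1}] − E[M(H2O)_n]``;
* per-first-shell-ligand interaction energy,
  ``E_I/N1 = (E[M(H2O)_n] − E(M) − E[(H2O)_n]) / N1`` with the water
  assembly evaluated frozen at the cluster geometry.

Plus a finite-difference harmonic analysis (mass-weighted Hessian,
rigid-body projection) giving ZPE and 298 K thermal corrections for
ranking near-degenerate isomers at 0 K vs finite temperature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import _kernels as K
from .geometry import ClusterGeometry
from .potential import EnergyModel, gradient

__all__ = [
    "FragmentEnergies",
    "ThermoResult",
    "counterpoise_bsse",
    "sequential_binding_energy",
    "interaction_energy_per_ligand",
    "harmonic_modes",
    "harmonic_thermo",
    "relative_energies",
    "ATOMIC_MASSES",
    "WAVENUMBER_PER_SQRT_LAMBDA",
    "KJ_PER_MOL_PER_WAVENUMBER",
]

# unit-bridge constants (CODATA 2018)
_H = 6.62607015e-34          # J s
_C_CM = 2.99792458e10        # cm/s
_NA = 6.02214076e23          # 1/mol
_KB = 1.380649e-23           # J/K
_R = _KB * _NA               # J/mol/K
_P0 = 101325.0               # Pa, standard pressure for translational entropy

#: cm^-1 per sqrt(kJ mol^-1 Å^-2 amu^-1)
WAVENUMBER_PER_SQRT_LAMBDA = 1e13 / (2.0 * np.pi * _C_CM)
#: kJ/mol of one quantum at 1 cm^-1
KJ_PER_MOL_PER_WAVENUMBER = _H * _C_CM * _NA / 1000.0

ATOMIC_MASSES = {"Ca": 40.078, "O": 15.999, "H": 1.008}  # amu

ENTROPY_FREQ_FLOOR = 10.0  # cm^-1, quasi-harmonic guard for entropy terms


@dataclass(frozen=True)
class FragmentEnergies:
    """Per-fragment (E in full basis, E in fragment basis) pairs, kJ/mol."""

    pairs: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "pairs", tuple((float(a), float(b)) for a, b in self.pairs)
        )
        if len(self.pairs) < 1:
            raise ValueError("need at least one fragment")

    @property
    def m(self) -> int:
        return len(self.pairs)


def counterpoise_bsse(fragments: FragmentEnergies) -> float:
    """Σ_i (E_i^full − E_i^fragment); exact arithmetic on the inputs."""
    return float(sum(a - b for a, b in fragments.pairs))


def sequential_binding_energy(
    e_water: float, e_n_minus_1: float, e_n: float
) -> float:
    """Energy released on adding one water: E(H2O) + E_{n−1} − E_n."""
    return float(e_water) + float(e_n_minus_1) - float(e_n)


def interaction_energy_per_ligand(
    e_cluster: float, e_ion: float, e_waters_frozen: float, n1: int
) -> float:
    """(E_cluster − E_ion − E_waters@cluster-geometry) / N1.

    ``e_waters_frozen`` must be the energy of the water assembly at the
    cluster geometry with the ion removed.
    """
    if n1 < 1:
        raise ValueError("interaction energy per ligand undefined for N1 = 0")
    return (float(e_cluster) - float(e_ion) - float(e_waters_frozen)) / n1


# ----------------------------------------------------------------------
# harmonic analysis
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class ModeAnalysis:
    """Projected normal modes of one structure."""

    all_frequencies: np.ndarray   # 3N signed wavenumbers incl. rigid ~0 modes
    frequencies: np.ndarray       # vibrational modes only, signed (cm^-1)
    n_rigid: int                  # 6, or 5 for linear structures
    linear: bool


def _rigid_projector(coords: np.ndarray, masses: np.ndarray) -> tuple[np.ndarray, int, bool]:
    """Orthonormal basis of mass-weighted rigid translations/rotations."""
    natoms = coords.shape[0]
    sq = np.sqrt(masses)
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    rel = coords - com
    vecs = []
    for ax in range(3):  # translations
        v = np.zeros((natoms, 3))
        v[:, ax] = sq
        vecs.append(v.ravel())
    # rotations about the principal axes of inertia
    inertia = np.zeros((3, 3))
    for i in range(natoms):
        r = rel[i]
        inertia += masses[i] * (np.dot(r, r) * np.eye(3) - np.outer(r, r))
    w, axes = np.linalg.eigh(inertia)
    linear = bool(w[0] < 1e-6 * max(w[-1], 1e-12))
    for k in range(3):
        v = np.cross(rel, axes[:, k][None, :]) * sq[:, None]
        vecs.append(v.ravel())
    basis = np.array(vecs).T  # (3N, 6)
    # orthonormalize, dropping rank-deficient directions (linear case)
    q, s, _ = np.linalg.svd(basis, full_matrices=False)
    keep = s > 1e-8 * s[0]
    return q[:, keep], int(keep.sum()), linear


def harmonic_modes(
    coords: np.ndarray,
    masses: np.ndarray,
    grad_fn: Callable[[np.ndarray], np.ndarray],
    step: float = 0.005,
) -> ModeAnalysis:
    """Normal-mode frequencies from central finite differences.

    ``grad_fn`` maps flat coordinates (3N,) to the flat energy gradient
    (kJ/mol/Å).  The mass-weighted Hessian is symmetrized, rigid
    translations/rotations are projected out, and signed wavenumbers
    are returned (negative = negative curvature).
    """
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    x = coords.ravel().copy()
    ndof = x.size

    def fd_hessian(h: float) -> np.ndarray:
        out = np.empty((ndof, ndof))
        for i in range(ndof):
            xi = x[i]
            x[i] = xi + h
            gp = np.asarray(grad_fn(x)).ravel().copy()
            x[i] = xi - h
            gm = np.asarray(grad_fn(x)).ravel()
            x[i] = xi
            out[i] = (gp - gm) / (2 * h)
        return out

    # Richardson extrapolation kills the O(h^2) truncation term, which
    # otherwise breaks rotational invariance of the soft-mode spectrum
    hess = (4.0 * fd_hessian(step / 2) - fd_hessian(step)) / 3.0
    asym = np.abs(hess - hess.T).max()
    scale = max(np.abs(hess).max(), 1.0)
    if asym > 1e-3 * scale:
        raise ValueError(
            f"finite-difference Hessian asymmetry {asym:.3g} exceeds tolerance"
        )
    hess = 0.5 * (hess + hess.T)
    sq = np.repeat(np.sqrt(masses), 3)
    hmw = hess / np.outer(sq, sq)
    q, n_rigid, linear = _rigid_projector(coords, masses)
    proj = np.eye(ndof) - q @ q.T
    hp = proj @ hmw @ proj
    lam = np.linalg.eigvalsh(0.5 * (hp + hp.T))
    freqs = np.sign(lam) * WAVENUMBER_PER_SQRT_LAMBDA * np.sqrt(np.abs(lam))
    order = np.argsort(np.abs(freqs))
    vib = np.sort(freqs[order[n_rigid:]])
    return ModeAnalysis(np.sort(freqs), vib, n_rigid, linear)


@dataclass(frozen=True)
class ThermoResult:
    """Harmonic frequencies, ZPE and RRHO thermal corrections (kJ/mol).

    ``thermal_correction_H``/``thermal_correction_G`` are the additive
    corrections to the potential-energy minimum: H(T) − E_min and
    G(T) − E_min for an ideal gas at 1 atm (ZPE included in both).
    Frequencies are raw signed wavenumbers; modes below the 10 cm⁻¹
    floor enter entropy terms at the floor value.
    """

    frequencies: np.ndarray
    zpe: float
    thermal_correction_H: float
    thermal_correction_G: float
    T: float
    n_imaginary: int
    vibrational_energy: float   # E_vib(T) incl. ZPE, kJ/mol
    entropy_vib: float          # J/mol/K
    entropy_rot: float
    entropy_trans: float
    linear: bool


def vibrational_energy(frequencies: np.ndarray, T: float) -> float:
    """Harmonic E_vib(T) = Σ hcν̃ [1/2 + 1/(e^x − 1)] in kJ/mol."""
    nu = np.asarray(frequencies, dtype=float)
    nu = nu[nu > 0]
    e = 0.5 * KJ_PER_MOL_PER_WAVENUMBER * nu.sum()
    if T > 0 and nu.size:
        x = KJ_PER_MOL_PER_WAVENUMBER * 1000.0 * nu / (_R * T)
        x = np.minimum(x, 700.0)  # frozen modes contribute nothing anyway
        e += float(np.sum(KJ_PER_MOL_PER_WAVENUMBER * nu / np.expm1(x)))
    return float(e)


def vibrational_entropy(frequencies: np.ndarray, T: float) -> float:
    """Harmonic S_vib in J/mol/K with the low-frequency floor applied."""
    nu = np.asarray(frequencies, dtype=float)
    nu = np.maximum(nu[nu > 0], ENTROPY_FREQ_FLOOR)
    if T <= 0 or nu.size == 0:
        return 0.0
    x = KJ_PER_MOL_PER_WAVENUMBER * 1000.0 * nu / (_R * T)
    x = np.minimum(x, 700.0)  # frozen modes contribute nothing anyway
    return float(_R * np.sum(x / np.expm1(x) - np.log1p(-np.exp(-x))))


def harmonic_thermo(
    geometry: ClusterGeometry,
    model: EnergyModel,
    T: float = 298.15,
    step: float = 0.005,
    gtol_warn: float = 1e-2,
) -> ThermoResult:
    """Full RRHO thermochemistry of a (converged) cluster minimum.

    The caller is expected to pass a relaxed structure; a residual
    gradient above ``gtol_warn`` or any negative-curvature mode flags
    the result (``n_imaginary`` > 0) rather than raising.
    """
    gmax = float(np.abs(gradient(geometry, model)).max())
    if gmax > gtol_warn:
        warnings.warn(
            f"structure has residual gradient {gmax:.3g} kJ/mol/Å; "
            "harmonic analysis assumes a stationary point",
            stacklevel=2,
        )
    coords = geometry.coordinates()
    masses = np.array(
        ["Ca"] + ["O", "H", "H"] * geometry.n, dtype=object
    )
    masses = np.array([ATOMIC_MASSES[el] for el in masses])
    params = model.param_vector()
    nw = geometry.n

    def grad_fn(x: np.ndarray) -> np.ndarray:
        _, g, status = K.energy_gradient(np.ascontiguousarray(x), params, nw)
        if status != K.STATUS_OK:
            raise ValueError("singular geometry during Hessian evaluation")
        return g

    modes = harmonic_modes(coords, masses, grad_fn, step)
    return thermo_from_modes(modes, masses, coords, T)


def thermo_from_modes(
    modes: ModeAnalysis,
    masses: np.ndarray,
    coords: np.ndarray,
    T: float,
) -> ThermoResult:
    """RRHO corrections from an existing mode analysis."""
    nu = modes.frequencies
    n_imag = int(np.sum(nu < -1.0))
    zpe = float(0.5 * KJ_PER_MOL_PER_WAVENUMBER * nu[nu > 0].sum())
    e_vib = vibrational_energy(nu, T)
    s_vib = vibrational_entropy(nu, T)
    # translation (Sackur–Tetrode) and rigid-rotor rotation
    mass_kg = masses.sum() / (_NA * 1000.0)
    rt_kj = _R * T / 1000.0
    if T > 0:
        q_trans = (2 * np.pi * mass_kg * _KB * T / _H**2) ** 1.5 * (_KB * T / _P0)
        s_trans = _R * (np.log(q_trans) + 2.5)
        com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
        rel = coords - com
        inertia = np.zeros((3, 3))
        for i in range(coords.shape[0]):
            r = rel[i]
            inertia += masses[i] * (np.dot(r, r) * np.eye(3) - np.outer(r, r))
        # amu Å^2 -> kg m^2
        moments = np.sort(np.linalg.eigvalsh(inertia)) * 1e-20 / (_NA * 1000.0)
        if modes.linear:
            i_eff = moments[-1]
            q_rot = 8 * np.pi**2 * i_eff * _KB * T / _H**2
            s_rot = _R * (np.log(q_rot) + 1.0)
            e_rot = rt_kj
        else:
            q_rot = (
                np.sqrt(np.pi * moments[0] * moments[1] * moments[2])
                * (8 * np.pi**2 * _KB * T / _H**2) ** 1.5
            )
            s_rot = _R * (np.log(q_rot) + 1.5)
            e_rot = 1.5 * rt_kj
        e_trans = 1.5 * rt_kj
        h_corr = e_vib + e_trans + e_rot + rt_kj  # + RT for H = U + pV
        g_corr = h_corr - T * (s_vib + s_trans + s_rot) / 1000.0
    else:
        s_trans = s_rot = 0.0
        h_corr = e_vib
        g_corr = e_vib
    return ThermoResult(
        frequencies=nu,
        zpe=zpe,
        thermal_correction_H=float(h_corr),
        thermal_correction_G=float(g_corr),
        T=float(T),
        n_imaginary=n_imag,
        vibrational_energy=float(e_vib),
        entropy_vib=float(s_vib),
        entropy_rot=float(s_rot),
        entropy_trans=float(s_trans),
        linear=modes.linear,
    )


def relative_energies(
    candidates: Sequence[tuple[ClusterGeometry, float]],
    thermo: Sequence[ThermoResult],
    T: float = 298.15,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Rank candidate isomers at 0 K (E_min + ZPE) and at T (E_min + G corr).

    Both columns are reported relative to each column's own minimum, so
    the most stable candidate reads 0 in each column; the ordering may
    differ between the two (entropic re-ranking).
    """
    if len(candidates) != len(thermo):
        raise ValueError("candidates and thermo results must align")
    if len(candidates) == 0:
        raise ValueError("need at least one candidate")
    ns = {g.n for g, _ in candidates}
    if len(ns) != 1:
        raise ValueError("all candidates must share the same water count")
    if labels is None:
        labels = [f"cand{i}" for i in range(len(candidates))]
    e0 = np.array([e + th.zpe for (_, e), th in zip(candidates, thermo)])
    et = np.array(
        [e + th.thermal_correction_G for (_, e), th in zip(candidates, thermo)]
    )
    return pd.DataFrame(
        {
            "label": list(labels),
            "E_min": [e for _, e in candidates],
            "ZPE": [th.zpe for th in thermo],
            "rel_0K": e0 - e0.min(),
            f"rel_{T:g}K": et - et.min(),
        }
    )
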