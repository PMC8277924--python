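import dataclasses

import numpy as np
import pytest

from hydrashell.energetics import (
    ATOMIC_MASSES,
    FragmentEnergies,
    KJ_PER_MOL_PER_WAVENUMBER,
    ThermoResult,
    WAVENUMBER_PER_SQRT_LAMBDA,
    counterpoise_bsse,
    harmonic_modes,
    harmonic_thermo,
    interaction_energy_per_ligand,
    relative_energies,
    sequential_binding_energy,
    vibrational_energy,
    vibrational_entropy,
)
from hydrashell.geometry import ClusterGeometry, random_rotation_matrix
from hydrashell.potential import local_minimize

_R = 8.31446261815324  # J/mol/K


# ----------------------------------------------------------------------
# exact arithmetic of the three bookkeeping operations
# ----------------------------------------------------------------------
def test_counterpoise_identical_bases_is_zero():
    assert counterpoise_bsse(FragmentEnergies(((-5.0, -5.0),))) == 0.0


def test_counterpoise_sums_fragment_differences():
    frags = FragmentEnergies(((-2.0, -1.0), (-3.5, -2.5), (0.0, 1.0)))
    assert counterpoise_bsse(frags) == pytest.approx(-3.0, abs=1e-14)


def test_counterpoise_rejects_empty_fragments():
    with pytest.raises(ValueError):
        FragmentEnergies(())


def test_sequential_binding_energy_identities():
    assert sequential_binding_energy(-10.0, -100.0, -110.0) == 0.0
    assert sequential_binding_energy(-10.0, -100.0, -160.0) == pytest.approx(50.0)


def test_interaction_energy_per_ligand_arithmetic():
    assert interaction_energy_per_ligand(-1200.0, 0.0, 0.0, 6) == pytest.approx(-200.0)
    # ion at infinite separation: numerator vanishes
    assert interaction_energy_per_ligand(-50.0, 0.0, -50.0, 4) == 0.0
    with pytest.raises(ValueError):
        interaction_energy_per_ligand(-1.0, 0.0, 0.0, 0)


# ----------------------------------------------------------------------
# harmonic analysis closed forms
# ----------------------------------------------------------------------
def diatomic_modes(k: float, m1: float, m2: float, r: float = 1.2):
    coords = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
    masses = np.array([m1, m2])

    def grad(x):
        x = x.reshape(2, 3)
        d = x[1] - x[0]
        rr = np.linalg.norm(d)
        dedr = 2.0 * k * (rr - r)
        g = np.zeros((2, 3))
        g[1] = dedr * d / rr
        g[0] = -g[1]
        return g.ravel()

    return harmonic_modes(coords, masses, grad)


def test_diatomic_frequency_and_zpe_closed_form():
    """V = k (r - r0)^2 gives omega = sqrt(2k/mu); ZPE = hbar omega / 2."""
    k, m1, m2 = 2000.0, 15.999, 1.008
    mu = m1 * m2 / (m1 + m2)
    modes = diatomic_modes(k, m1, m2)
    assert modes.linear
    assert modes.n_rigid == 5
    assert len(modes.frequencies) == 1
    nu_expected = WAVENUMBER_PER_SQRT_LAMBDA * np.sqrt(2.0 * k / mu)
    assert modes.frequencies[0] == pytest.approx(nu_expected, rel=1e-6)
    zpe = 0.5 * KJ_PER_MOL_PER_WAVENUMBER * modes.frequencies[0]
    assert zpe == pytest.approx(
        0.5 * KJ_PER_MOL_PER_WAVENUMBER * nu_expected, rel=1e-6
    )


def test_vibrational_energy_low_and_high_temperature_limits():
    nu = np.array([800.0])
    zpe = 0.5 * KJ_PER_MOL_PER_WAVENUMBER * nu.sum()
    # T -> 0: thermal vibrational energy collapses to the ZPE, entropy to 0
    assert vibrational_energy(nu, 0.0) == pytest.approx(zpe, rel=1e-12)
    assert vibrational_entropy(nu, 1.0) == pytest.approx(0.0, abs=1e-10)
    # equipartition: E_vib -> kB T per mode once kB T >= 20 h c nu
    t_high = 20.0 * KJ_PER_MOL_PER_WAVENUMBER * 1000.0 * nu[0] / _R
    e_thermal = vibrational_energy(nu, t_high)
    assert e_thermal == pytest.approx(_R * t_high / 1000.0, rel=0.01)


def test_cluster_modes_have_six_near_zero_after_projection(model, random_clusters):
    res = local_minimize(random_clusters(2, seed=31), model)
    th = harmonic_thermo(res.geometry, model)
    assert th.n_imaginary == 0
    assert th.zpe > 0


def test_projection_removes_exactly_six_rigid_modes(model, random_clusters):
    from hydrashell import _kernels as K
    from hydrashell.energetics import _rigid_projector

    res = local_minimize(random_clusters(2, seed=31), model)
    geom = res.geometry
    params = model.param_vector()

    def grad(x):
        _, g, _ = K.energy_gradient(np.ascontiguousarray(x), params, geom.n)
        return g

    coords = geom.coordinates()
    masses = np.array([ATOMIC_MASSES[el] for el in ["Ca"] + ["O", "H", "H"] * geom.n])
    modes = harmonic_modes(coords, masses, grad)
    near_zero = np.abs(modes.all_frequencies) < 1.0
    assert near_zero.sum() == 6
    assert len(modes.frequencies) == 3 * geom.n_atoms - 6
    # the unprojected spectrum (same extrapolated Hessian, no rigid-body
    # projection) differs only in the six near-zero modes
    x = coords.ravel()
    hess = (
        4.0 * K.fd_hessian(x, params, geom.n, 0.0025)
        - K.fd_hessian(x, params, geom.n, 0.005)
    ) / 3.0
    sq = np.repeat(np.sqrt(masses), 3)
    lam = np.linalg.eigvalsh(hess / np.outer(sq, sq))
    raw = np.sign(lam) * WAVENUMBER_PER_SQRT_LAMBDA * np.sqrt(np.abs(lam))
    raw_vib = np.sort(raw[np.argsort(np.abs(raw))[6:]])
    np.testing.assert_allclose(raw_vib, modes.frequencies, atol=1.0)


def test_thermo_invariant_under_rigid_motion(model, random_clusters):
    res = local_minimize(random_clusters(2, seed=33), model)
    rng = np.random.default_rng(5)
    moved = res.geometry.rotated(random_rotation_matrix(rng)).translated([3.0, 2.0, 1.0])
    a = harmonic_thermo(res.geometry, model)
    b = harmonic_thermo(moved, model)
    assert b.zpe == pytest.approx(a.zpe, abs=1e-4)
    assert b.thermal_correction_G == pytest.approx(a.thermal_correction_G, abs=1e-4)


# ----------------------------------------------------------------------
# isomer ranking
# ----------------------------------------------------------------------
def fake_thermo(zpe: float, g_corr: float) -> ThermoResult:
    return ThermoResult(
        frequencies=np.array([100.0]),
        zpe=zpe,
        thermal_correction_H=g_corr,
        thermal_correction_G=g_corr,
        T=298.15,
        n_imaginary=0,
        vibrational_energy=zpe,
        entropy_vib=0.0,
        entropy_rot=0.0,
        entropy_trans=0.0,
        linear=False,
    )


def dummy_geometry(n: int = 2, seed: int = 0):
    from hydrashell.ga import random_cluster

    return random_cluster(n, np.random.default_rng(seed))


def test_relative_energies_single_candidate_is_zero():
    table = relative_energies(
        [(dummy_geometry(), -100.0)], [fake_thermo(10.0, 12.0)]
    )
    assert table["rel_0K"].iloc[0] == 0.0
    assert table.filter(like="rel_2").iloc[0, 0] == 0.0


def test_relative_energies_zpe_gap():
    cands = [(dummy_geometry(seed=1), -100.0), (dummy_geometry(seed=2), -100.0)]
    thermos = [fake_thermo(10.0, 12.0), fake_thermo(11.0, 13.0)]
    table = relative_energies(cands, thermos)
    assert list(table["rel_0K"]) == pytest.approx([0.0, 1.0])


def test_relative_energies_detects_rank_swap():
    """Planted entropy difference reverses the 0 K ordering at 298 K."""
    cands = [(dummy_geometry(seed=1), -100.0), (dummy_geometry(seed=2), -99.5)]
    # candidate 0 wins at 0 K (lower E_min + ZPE) but carries a much
    # larger free-energy correction, so candidate 1 wins at 298 K
    thermos = [fake_thermo(zpe=0.0, g_corr=10.0), fake_thermo(zpe=0.0, g_corr=0.0)]
    table = relative_energies(cands, thermos)
    rel0 = table["rel_0K"].to_numpy()
    relt = table.filter(like="rel_2").to_numpy()[:, 0]
    assert rel0[0] == 0.0 and rel0[1] > 0.0
    assert relt[1] == 0.0 and relt[0] > 0.0


def test_relative_energies_input_validation():
    with pytest.raises(ValueError):
        relative_energies([], [])
    with pytest.raises(ValueError):
        relative_energies([(dummy_geometry(), -1.0)], [])
    with pytest.raises(ValueError):
        relative_energies(
            [(dummy_geometry(2), -1.0), (dummy_geometry(3, seed=1), -1.0)],
            [fake_thermo(0, 0), fake_thermo(0, 0)],
        )
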