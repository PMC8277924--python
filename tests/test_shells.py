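import warnings

import numpy as np
import pytest

from hydrashell.fixtures import FixtureSpec, build_fixture, random_feasible_spec
from hydrashell.geometry import ClusterGeometry, random_rotation_matrix
from hydrashell.shells import (
    HBond,
    HBondCriterion,
    HBondGraph,
    assign_shells,
    detect_hbonds,
    first_shell_hbond_count,
    shell_distances,
    shell_series,
)

from conftest import water_at

# the motif reported for the 10-water cluster: six first-shell waters,
# four second-shell acceptors on distinct donors
N10_SPEC = FixtureSpec(
    n1=6,
    n2=4,
    hbond_edges=((0, 6), (1, 7), (2, 8), (3, 9)),
    shell_radii=(2.385, 4.257, 5.60),
    jitter=0.0,
    rng_seed=7,
)


def ideal_dimer(d_oo: float = 2.8) -> ClusterGeometry:
    """Linear water dimer far from the ion; donor H on the O-O axis."""
    donor_o = np.array([6.0, 0.0, 0.0])
    acceptor_o = donor_o + np.array([d_oo, 0.0, 0.0])
    donor = water_at(donor_o, h1_dir=[1.0, 0.0, 0.0])
    acceptor = water_at(acceptor_o, bisector=[1.0, 0.0, 0.0])
    return ClusterGeometry(np.zeros(3), 2, (donor, acceptor))


def test_criterion_validation():
    with pytest.raises(ValueError):
        HBondCriterion(min_OHO_angle=181.0)
    with pytest.raises(ValueError):
        HBondCriterion(max_OO_distance=-1.0)


def test_single_water_has_no_bonds(one_water):
    assert detect_hbonds(one_water).n_hb == 0


def test_ideal_linear_dimer_detected_with_correct_donor():
    hb = detect_hbonds(ideal_dimer())
    assert hb.n_hb == 1
    (edge,) = hb.edges
    assert (edge.donor, edge.acceptor, edge.h_index) == (0, 1, 0)


def test_stretched_dimer_beyond_cutoff():
    assert detect_hbonds(ideal_dimer(4.0)).n_hb == 0


def test_one_bond_per_donor_hydrogen_pair():
    """Both donor hydrogens aimed at one acceptor give a single edge."""
    donor_o = np.array([6.0, 0.0, 0.0])
    acceptor_o = np.array([8.6, 0.0, 0.0])
    # hydrogens symmetric about the O-O axis, both within the criterion
    donor = water_at(donor_o, bisector=[1.0, 0.0, 0.0], theta=np.deg2rad(30.0))
    acceptor = water_at(acceptor_o, bisector=[1.0, 0.0, 0.0])
    geom = ClusterGeometry(np.zeros(3), 2, (donor, acceptor))
    hb = detect_hbonds(geom)
    assert hb.n_hb == 1


def test_n10_motif_counts_and_distances():
    geom, _, _ = build_fixture(N10_SPEC)
    hb = detect_hbonds(geom)
    sh = assign_shells(geom, hb)
    rep = shell_distances(geom, sh, hb)
    assert (sh.n1, sh.n2, sh.n3) == (6, 4, 0)
    assert hb.n_hb == 4
    assert rep.mean_CaO_shell1 == pytest.approx(2.385, abs=1e-9)
    assert rep.mean_CaO_shell2 == pytest.approx(4.257, abs=1e-9)
    assert first_shell_hbond_count(sh, hb) == 0


def test_single_first_shell_water():
    geom = ClusterGeometry(
        np.zeros(3), 2, (water_at([2.4, 0, 0], bisector=[1, 0, 0]),)
    )
    sh = assign_shells(geom, detect_hbonds(geom))
    assert (sh.n1, sh.n2, sh.n3) == (1, 0, 0)


def test_chain_shells_follow_graph_distance():
    """Ca - w0 - w1 - w2 hydrogen-bond chain puts one water per shell."""
    w0 = water_at([2.4, 0, 0], h1_dir=[1, 0, 0])
    o1 = np.array([2.4 + 2.8, 0, 0])
    w1 = water_at(o1, h1_dir=[1, 0, 0])
    w2 = water_at(o1 + [2.8, 0, 0], bisector=[1, 0, 0])
    geom = ClusterGeometry(np.zeros(3), 2, (w0, w1, w2))
    hb = detect_hbonds(geom)
    sh = assign_shells(geom, hb)
    assert sh.shell_index == (1, 2, 3)
    assert (sh.n1, sh.n2, sh.n3) == (1, 1, 1)


def test_two_first_shell_waters_bonded_count_once():
    d1 = np.array([3.0, 0.0, 0.0])
    theta = 2.0 * np.arcsin(3.3 / 2.0 / 3.0)
    d2 = 3.0 * np.array([np.cos(theta), np.sin(theta), 0.0])
    w1 = water_at(d1, h1_dir=d2 - d1)  # donates toward w2
    w2 = water_at(d2, bisector=d2)
    geom = ClusterGeometry(np.zeros(3), 2, (w1, w2))
    hb = detect_hbonds(geom)
    sh = assign_shells(geom, hb)
    assert sh.n1 == 2
    assert hb.n_hb == 1
    assert first_shell_hbond_count(sh, hb) == 1


def test_first_shell_hbond_count_empty_graph():
    sh = assign_shells(
        ClusterGeometry(np.zeros(3), 2, (water_at([2.4, 0, 0], bisector=[1, 0, 0]),)),
        HBondGraph(()),
    )
    assert first_shell_hbond_count(sh, HBondGraph(())) == 0


def test_mean_oo_is_arithmetic_mean():
    """Two planted bonds with O-O 2.7 and 2.9 average to 2.8."""
    w0 = water_at([2.4, 0, 0], h1_dir=[1, 0, 0])
    w1 = water_at([2.4 + 2.7, 0, 0], bisector=[1, 0, 0])
    w2 = water_at([-2.4, 0, 0], h1_dir=[-1, 0, 0])
    w3 = water_at([-2.4 - 2.9, 0, 0], bisector=[-1, 0, 0])
    geom = ClusterGeometry(np.zeros(3), 2, (w0, w1, w2, w3))
    hb = detect_hbonds(geom)
    assert hb.edge_set() == {(0, 1), (2, 3)}
    sh = assign_shells(geom, hb)
    rep = shell_distances(geom, sh, hb)
    assert rep.mean_OO_hbonded == pytest.approx(2.8, abs=1e-9)


def test_report_invariant_under_permutation_and_rigid_motion():
    geom, _, _ = build_fixture(N10_SPEC)
    rng = np.random.default_rng(3)
    moved = (
        geom.rotated(random_rotation_matrix(rng))
        .translated([5.0, 1.0, -2.0])
        .permuted(rng.permutation(geom.n))
    )
    for g in (geom, moved):
        hb = detect_hbonds(g)
        sh = assign_shells(g, hb)
        rep = shell_distances(g, sh, hb)
        assert (sh.n1, sh.n2, sh.n3) == (6, 4, 0)
        assert rep.mean_CaO_shell1 == pytest.approx(2.385, abs=1e-6)
        assert hb.n_hb == 4


def test_loosening_oo_cutoff_never_decreases_nhb():
    rng = np.random.default_rng(10)
    for _ in range(10):
        geom, _, _ = build_fixture(random_feasible_spec(rng))
        previous = -1
        for cutoff in (3.0, 3.3, 3.5, 3.8, 4.2):
            n_hb = detect_hbonds(geom, HBondCriterion(max_OO_distance=cutoff)).n_hb
            assert n_hb >= previous
            previous = n_hb


def test_shell_conservation_on_random_fixtures():
    rng = np.random.default_rng(20)
    for _ in range(20):
        geom, _, _ = build_fixture(random_feasible_spec(rng))
        sh = assign_shells(geom, detect_hbonds(geom))
        assert sh.n1 + sh.n2 + sh.n3 + len(sh.unassigned) == geom.n


def test_degenerate_structure_without_first_shell_uses_fallback():
    geom = ClusterGeometry(
        np.zeros(3), 2, (water_at([4.5, 0, 0], bisector=[1, 0, 0]),)
    )
    with pytest.warns(UserWarning, match="degenerate"):
        sh = assign_shells(geom, detect_hbonds(geom))
    assert sh.shell_index == (2,)
    assert sh.fallback == (0,)


def test_shell_series_matches_planted_motifs():
    """Size series 10-12 with one extra second-shell acceptor per step."""
    specs = {
        10: N10_SPEC,
        11: FixtureSpec(
            n1=6, n2=5, hbond_edges=((0, 6), (1, 7), (2, 8), (3, 9), (4, 10)),
            shell_radii=(2.381, 4.275, 5.6), jitter=0.0, rng_seed=8,
        ),
        12: FixtureSpec(
            n1=6, n2=6,
            hbond_edges=((0, 6), (1, 7), (2, 8), (3, 9), (4, 10), (5, 11)),
            shell_radii=(2.380, 4.281, 5.6), jitter=0.0, rng_seed=9,
        ),
    }
    geoms = {n: build_fixture(s)[0] for n, s in specs.items()}
    table = shell_series(geoms)
    assert list(table["n"]) == [10, 11, 12]
    assert list(table["N1"]) == [6, 6, 6]
    assert list(table["N2"]) == [4, 5, 6]
    # shuffled input gives the identical sorted table
    shuffled = shell_series({12: geoms[12], 10: geoms[10], 11: geoms[11]})
    assert shuffled.equals(table)
    single = shell_series({10: geoms[10]})
    assert len(single) == 1
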