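import dataclasses

import numpy as np
import pytest

from hydrashell.ga import (
    GAConfig,
    crossover_cut_splice,
    evolve,
    init_population,
    is_duplicate,
    mutate,
    random_cluster,
)
from hydrashell.geometry import ClusterGeometry, random_rotation_matrix
from hydrashell.potential import energy, local_minimize

from conftest import water_at

SMALL = GAConfig(population_size=6, max_generations=40, stall_generations=15)


def spread_cluster(radii, seed=0):
    """Well-separated waters at given ion distances (no repair needed)."""
    rng = np.random.default_rng(seed)
    dirs = np.eye(3).tolist() + (-np.eye(3)).tolist()
    waters = [
        water_at(np.asarray(d) * r, bisector=np.asarray(d)) for d, r in zip(dirs, radii)
    ]
    return ClusterGeometry(np.zeros(3), 2, waters)


def test_config_validation():
    with pytest.raises(ValueError):
        GAConfig(population_size=2)
    with pytest.raises(ValueError):
        GAConfig(crossover_probability=1.5)
    with pytest.raises(ValueError):
        GAConfig(mutation_weights={"bogus": 1.0})
    with pytest.raises(ValueError):
        GAConfig(dedup_energy_tol=0.0)


def test_random_cluster_respects_bounds_and_validity():
    rng = np.random.default_rng(8)
    for _ in range(5):
        geom = random_cluster(10, rng, radius_bounds=(2.2, 5.5))
        geom.validate()
        d = geom.ion_oxygen_distances()
        assert np.all((d >= 2.2) & (d <= 5.5))


def test_init_population_single_basin_dedups_to_one(model):
    """All n=1 starts fall into the same basin; the pool keeps one entry."""
    cfg = dataclasses.replace(SMALL, population_size=4, rng_seed=3)
    pool = init_population(1, cfg, model)
    assert len(pool) == 1


def test_init_population_seeded_determinism(model):
    cfg = dataclasses.replace(SMALL, rng_seed=17)
    a = init_population(2, cfg, model)
    b = init_population(2, cfg, model)
    assert len(a) == len(b)
    for ea, eb in zip(a.entries, b.entries):
        assert ea.energy == eb.energy
        np.testing.assert_array_equal(
            ea.geometry.coordinates(), eb.geometry.coordinates()
        )


def test_crossover_conserves_water_count():
    rng = np.random.default_rng(5)
    pa = spread_cluster([2.4, 4.3], seed=1)
    pb = spread_cluster([2.5, 4.4], seed=2)
    for _ in range(1000):
        child = crossover_cut_splice(pa, pb, rng)
        assert child.n == 2
        child.validate()


def test_crossover_child_waters_come_from_parents():
    pa = spread_cluster([2.4, 4.3, 5.2], seed=3)
    pb = spread_cluster([2.6, 4.5, 5.4], seed=4)
    parent_oxy = np.vstack([pa.oxygen_positions(), pb.oxygen_positions()])
    rng = np.random.default_rng(9)
    for _ in range(50):
        child = crossover_cut_splice(pa, pb, rng)
        for w in child.waters:
            d = np.linalg.norm(parent_oxy - w.oxygen, axis=1)
            assert d.min() < 1e-9  # splice copies coordinates verbatim


def test_crossover_of_identical_parents_stays_in_basin(model):
    parent = local_minimize(random_cluster(3, np.random.default_rng(1)), model)
    rng = np.random.default_rng(2)
    child = crossover_cut_splice(parent.geometry, parent.geometry, rng)
    res = local_minimize(child, model)
    assert res.energy <= parent.energy + 1e-6


def test_mutate_rotate_water_moves_hydrogens_only(one_water):
    rng = np.random.default_rng(1)
    out = mutate(one_water, rng, {"rotate_water": 1.0})
    np.testing.assert_array_equal(out.waters[0].oxygen, one_water.waters[0].oxygen)
    assert np.abs(out.waters[0].hydrogens - one_water.waters[0].hydrogens).max() > 1e-6


def test_mutate_shell_hop_moves_one_water_radially():
    geom = spread_cluster([2.4, 4.3], seed=6)
    rng = np.random.default_rng(3)
    out = mutate(geom, rng, {"shell_hop": 1.0})
    d0 = geom.ion_oxygen_distances()
    d1 = out.ion_oxygen_distances()
    changed = np.abs(d1 - d0) > 1e-9
    assert changed.sum() == 1
    assert 1.5 - 1e-9 <= np.abs(d1 - d0)[changed][0] <= 2.5 + 1e-9


def test_mutate_seeded_determinism(random_clusters):
    geom = random_clusters(4, seed=2)
    a = mutate(geom, np.random.default_rng(7))
    b = mutate(geom, np.random.default_rng(7))
    np.testing.assert_array_equal(a.coordinates(), b.coordinates())


def test_duplicate_detection_invariances(random_clusters):
    geom = random_clusters(5, seed=4)
    cfg = GAConfig()
    rng = np.random.default_rng(0)
    copy = (
        geom.rotated(random_rotation_matrix(rng))
        .translated([1.0, 2.0, 3.0])
        .permuted(rng.permutation(5))
    )
    assert is_duplicate(geom, copy, -100.0, -100.0, cfg)
    # mirror image: all distances preserved -> duplicate (documented limitation)
    mirror = geom.rotated(np.diag([1.0, 1.0, -1.0]))
    assert is_duplicate(geom, mirror, -100.0, -100.0, cfg)


def test_duplicate_detection_distinguishes_moved_water(random_clusters):
    geom = random_clusters(5, seed=4)
    cfg = GAConfig()
    waters = list(geom.waters)
    waters[0] = waters[0].translated(np.array([2.0, 0.0, 0.0]))
    other = geom.with_waters(waters)
    assert not is_duplicate(geom, other, -100.0, -100.0, cfg)


def test_evolve_single_water_matches_init_basin(model):
    cfg = dataclasses.replace(SMALL, rng_seed=5)
    pool = evolve(1, model, cfg)
    ref = init_population(1, dataclasses.replace(cfg, rng_seed=99), model)
    assert pool.best.energy == pytest.approx(ref.best.energy, abs=1e-6)


def test_evolve_best_trace_is_monotone(model):
    cfg = dataclasses.replace(SMALL, rng_seed=6)
    pool = evolve(2, model, cfg)
    trace = np.array(pool.best_trace)
    assert np.all(np.diff(trace) <= 1e-12)


def test_evolve_seeded_determinism(model):
    cfg = dataclasses.replace(SMALL, rng_seed=12)
    a = evolve(2, model, cfg)
    b = evolve(2, model, cfg)
    assert [e.energy for e in a.entries] == [e.energy for e in b.entries]
    for ea, eb in zip(a.entries, b.entries):
        np.testing.assert_array_equal(
            ea.geometry.coordinates(), eb.geometry.coordinates()
        )


def test_evolve_conserves_composition(model):
    cfg = dataclasses.replace(SMALL, rng_seed=8)
    pool = evolve(3, model, cfg)
    for entry in pool.entries:
        assert entry.geometry.n == 3
        entry.geometry.validate()
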