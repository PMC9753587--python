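"""SASA, osmotic-pressure reduction, molality, clusters and polymer statistics."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import sugarcg.analysis as A
from sugarcg.errors import SugarCGError
from sugarcg.mapping import map_coordinates
from sugarcg.pipeline import build_ideal_topology
from sugarcg.fitting import generate_synthetic_reference
from sugarcg.topology import ScalingPolicy


class TestBeadRadius:
    @pytest.mark.parametrize("sigma", [0.47, 0.41, 0.34, 0.25])
    def test_matches_numerical_lj_minimum(self, sigma):
        lj = lambda r: 4.0 * ((sigma / r) ** 12 - (sigma / r) ** 6)
        res = minimize_scalar(lj, bounds=(0.5 * sigma, 3 * sigma), method="bounded")
        assert A.bead_radius(sigma=sigma) == pytest.approx(res.x / 2.0, abs=1e-6)

    def test_size_class_lookup(self):
        assert A.bead_radius(size="regular") == pytest.approx(A.bead_radius(sigma=0.47))

    def test_non_positive_sigma_raises(self):
        with pytest.raises(SugarCGError):
            A.bead_radius(sigma=0.0)


def mc_sasa_oracle(xyz, radii, probe, n_points=200_000, seed=0):
    """Monte-Carlo surface integration: random points per extended sphere."""
    rng = np.random.default_rng(seed)
    ext = np.asarray(radii, dtype=float) + probe
    active = np.flatnonzero(np.asarray(radii) > 0)
    total = 0.0
    for i in active:
        pts = rng.normal(size=(n_points, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts = xyz[i] + ext[i] * pts
        outside = np.ones(n_points, dtype=bool)
        for j in active:
            if j == i:
                continue
            outside &= np.einsum("ij,ij->i", pts - xyz[j], pts - xyz[j]) >= ext[j] ** 2
        total += 4.0 * math.pi * ext[i] ** 2 * outside.mean()
    return total


class TestCgSasa:
    def test_single_regular_bead_closed_form(self):
        area = A.cg_sasa(np.zeros((1, 3)), [0.264])
        assert area == pytest.approx(4.0 * math.pi * (0.264 + 0.191) ** 2, rel=1e-9)

    def test_two_coincident_beads_expose_one_sphere(self):
        area = A.cg_sasa(np.zeros((2, 3)), [0.264, 0.264])
        assert area == pytest.approx(4.0 * math.pi * (0.264 + 0.191) ** 2, rel=1e-9)

    def test_glucose_structure_agrees_with_monte_carlo_oracle(self):
        top = build_ideal_topology("GLC")
        ref = generate_synthetic_reference("GLC", n_frames=1, seed=0)
        frame = map_coordinates(ref.coords[0], ref.index)
        radii = A.topology_radii(top)
        got = A.cg_sasa(frame.positions, radii)
        oracle = mc_sasa_oracle(frame.positions, radii, 0.191)
        assert got == pytest.approx(oracle, rel=0.01)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_random_bead_clusters_agree_with_monte_carlo_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        xyz = rng.uniform(0, 0.6, size=(n, 3))
        radii = rng.choice([0.264, 0.230, 0.191], size=n)
        got = A.cg_sasa(xyz, radii)
        oracle = mc_sasa_oracle(xyz, radii, 0.191, seed=seed)
        assert got == pytest.approx(oracle, rel=0.01)

    def test_monotone_in_probe_radius(self, rng):
        xyz = rng.uniform(0, 0.5, size=(5, 3))
        radii = [0.23] * 5
        areas = [
            A.cg_sasa(xyz, radii, A.SasaParams(probe_radius=p)) for p in (0.1, 0.191, 0.3)
        ]
        assert areas[0] < areas[1] < areas[2]

    def test_rotation_translation_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        xyz = rng.uniform(0, 0.5, size=(5, 3))
        radii = [0.264, 0.23, 0.23, 0.191, 0.23]
        rot = Rotation.random(rng=rng).as_matrix()
        params = A.SasaParams(n_sphere_points=4000)
        a1 = A.cg_sasa(xyz, radii, params)
        a2 = A.cg_sasa(xyz @ rot.T + 5.0, radii, params)
        assert a2 == pytest.approx(a1, rel=2e-3)

    def test_scaled_rings_have_larger_sasa_than_unscaled(self):
        areas = {}
        for scale in (1.0, 1.15):
            top = build_ideal_topology("GLC", scaling=ScalingPolicy(ring_scale=scale))
            # realize bead positions consistent with the scaled constraints
            lengths = [t.params[0] for t in top.terms_of("constraint")]
            r12, r13, r23 = lengths
            p1 = np.zeros(3)
            p2 = np.array([r12, 0.0, 0.0])
            x3 = (r12**2 + r13**2 - r23**2) / (2 * r12)
            p3 = np.array([x3, math.sqrt(max(r13**2 - x3**2, 0.0)), 0.0])
            xyz = np.vstack([p1, p2, p3])
            areas[scale] = A.cg_sasa(xyz, A.topology_radii(top)[:3])
        assert areas[1.15] > areas[1.0]

    def test_empty_structure_raises(self):
        with pytest.raises(SugarCGError, match="empty"):
            A.cg_sasa(np.zeros((0, 3)), [])


class TestOsmoticSystem:
    def test_default_geometry_reproduces_the_protocol(self):
        setup = A.OsmoticSetup()
        assert setup.box == (5.04156, 5.04156, 10.08312)
        assert setup.wall_offset == 2.52078
        assert setup.wall_force_constant == 1000.0
        zc = setup.box[2] / 2.0
        assert setup.wall_planes == (zc - 2.52078, zc + 2.52078)

    def test_solutes_confined_between_the_walls(self):
        setup = A.OsmoticSetup(n_solute=12, n_solvent=100)
        system = A.build_osmotic_system(np.zeros((1, 3)), setup, seed=3)
        z = system.positions[system.is_solute, 2]
        lo, hi = setup.wall_planes
        assert (z > lo).all() and (z < hi).all()
        assert len(system.restraints) == 12

    def test_zero_solutes_gives_pure_solvent_and_no_restraints(self):
        setup = A.OsmoticSetup(n_solute=0, n_solvent=50)
        system = A.build_osmotic_system(np.zeros((1, 3)), setup, seed=0)
        assert len(system.positions) == 50
        assert system.restraints == []

    def test_deterministic_for_fixed_seed(self):
        setup = A.OsmoticSetup(n_solute=5, n_solvent=30)
        s1 = A.build_osmotic_system(np.zeros((1, 3)), setup, seed=9)
        s2 = A.build_osmotic_system(np.zeros((1, 3)), setup, seed=9)
        assert np.array_equal(s1.positions, s2.positions)


class TestOsmoticPressure:
    def test_zero_forces_give_zero_pressure(self):
        s = A.WallForceSeries(np.arange(10.0), np.zeros(10), np.zeros(10))
        pi, err = A.osmotic_pressure(s, 25.0)
        assert pi == 0.0

    def test_constant_force_unit_conversion(self):
        # 100 kJ/mol/nm per wall over 25.417 nm^2 = 3.9344 kJ/mol/nm^3 = 65.33 bar
        s = A.WallForceSeries(np.arange(10.0), np.full(10, 100.0), np.full(10, 100.0))
        pi, err = A.osmotic_pressure(s, 25.417)
        assert pi == pytest.approx(65.33, abs=0.01)
        assert err == 0.0

    def test_linearity_in_the_forces(self, rng):
        lo, hi = rng.random(50), rng.random(50)
        s1 = A.WallForceSeries(np.arange(50.0), lo, hi)
        s3 = A.WallForceSeries(np.arange(50.0), 3 * lo, 3 * hi)
        assert A.osmotic_pressure(s3, 10.0)[0] == pytest.approx(3 * A.osmotic_pressure(s1, 10.0)[0])

    def test_non_positive_area_raises(self):
        s = A.WallForceSeries([0.0], [1.0], [1.0])
        with pytest.raises(SugarCGError):
            A.osmotic_pressure(s, 0.0)

    def test_ideal_solution_approaches_van_t_hoff(self):
        from scipy import constants

        setup = A.OsmoticSetup(n_solute=40, temperature=298.15)
        series = A.ideal_wall_force_series(setup, n_frames=6000, seed=12)
        pi, err = A.osmotic_pressure(series, setup.area_xy)
        slab_volume_L = setup.area_xy * 2 * setup.wall_offset * 1e-27 * 1e3
        conc = setup.n_solute / constants.N_A / slab_volume_L  # mol/L
        vant_hoff = conc * (constants.R * 1e-2) * setup.temperature  # L bar / (mol K)
        assert pi == pytest.approx(vant_hoff, rel=0.05)


class TestMolality:
    def test_zero_molarity_gives_zero_molality(self):
        assert A.molar_to_molal(A.ConcentrationSpec(0.0, 1.0, 0.18)) == 0.0

    def test_hand_checkable_example(self):
        spec = A.ConcentrationSpec(molarity=1.0, density=1.180, molar_mass=0.180)
        assert A.molar_to_molal(spec) == pytest.approx(1.000)

    def test_dilute_limit_molality_approaches_molarity(self):
        spec = A.ConcentrationSpec(molarity=1e-4, density=1.0, molar_mass=0.342)
        assert A.molar_to_molal(spec) == pytest.approx(1e-4, rel=1e-4)

    def test_no_solvent_mass_raises(self):
        with pytest.raises(SugarCGError):
            A.ConcentrationSpec(molarity=10.0, density=1.0, molar_mass=0.18)


def union_find_oracle(xyz, box, cutoff):
    n = len(xyz)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            d = xyz[i] - xyz[j]
            d -= box * np.round(d / box)
            if np.dot(d, d) < cutoff**2:
                parent[find(i)] = find(j)
    roots = {}
    for i in range(n):
        roots.setdefault(find(i), 0)
        roots[find(i)] += 1
    hist = {}
    for size in roots.values():
        hist[size] = hist.get(size, 0) + 1
    return hist


class TestClusters:
    def test_two_linkers_below_cutoff_form_one_pair(self):
        xyz = np.array([[0.0, 0.0, 0.0], [1.3, 0.0, 0.0]])
        assert A.cluster_sizes(xyz, [10.0, 10.0, 10.0]) == {2: 1}

    def test_all_far_apart_are_singletons(self):
        xyz = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [0.0, 2.0, 0.0]])
        assert A.cluster_sizes(xyz, [10.0, 10.0, 10.0]) == {1: 3}

    @pytest.mark.parametrize("seed", range(20))
    def test_random_periodic_points_match_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        box = np.array([8.0, 8.0, 8.0])
        xyz = rng.uniform(0, 8.0, size=(200, 3))
        got = A.cluster_sizes(xyz, box)
        assert got == union_find_oracle(xyz, box, 1.4)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_total_particle_count_is_conserved(self, seed):
        rng = np.random.default_rng(seed)
        xyz = rng.uniform(0, 6.0, size=(150, 3))
        hist = A.cluster_sizes(xyz, [6.0, 6.0, 6.0])
        assert sum(s * c for s, c in hist.items()) == 150


class TestPolymerStats:
    def test_single_bead_has_zero_radius_of_gyration(self):
        rg = A.radius_of_gyration(np.zeros((3, 1, 3)), [0])
        assert rg == pytest.approx(np.zeros(3))

    def test_rigid_rod_closed_forms(self):
        n, a = 10, 0.5
        xyz = np.zeros((1, n, 3))
        xyz[0, :, 0] = a * np.arange(n)
        stats = A.polymer_stats(xyz, list(range(n)))
        assert stats.ree[0] == pytest.approx((n - 1) * a)
        assert stats.rg[0] ** 2 == pytest.approx(a**2 * (n**2 - 1) / 12.0)

    def test_random_walk_matches_direct_formula(self, rng):
        xyz = rng.normal(size=(50, 20, 3))
        rg = A.radius_of_gyration(xyz, list(range(20)))
        for f in range(50):
            com = xyz[f].mean(axis=0)
            direct = math.sqrt(np.sum((xyz[f] - com) ** 2) / 20)
            assert rg[f] == pytest.approx(direct, abs=1e-12)

    def test_short_chain_end_to_end_is_an_error(self):
        with pytest.raises(SugarCGError, match="length < 2"):
            A.polymer_stats(np.zeros((2, 1, 3)), [0])
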