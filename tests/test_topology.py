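"""Topology assembly: constraints, virtual sites, bonded terms, exclusions, itp I/O."""

import numpy as np
import networkx as nx
import pytest

from sugarcg.errors import MissingParameterError
from sugarcg.graph import parse_glycan
from sugarcg.mapping import build_mapping_index, map_coordinates
from sugarcg.pipeline import build_ideal_topology
from sugarcg.topology import (
    BondedTerm,
    ExclusionPolicy,
    ScalingPolicy,
    assign_exclusions,
    build_beads,
    default_exclusion_policy,
    derive_ring_geometry,
    enumerate_bonded_terms,
    parse_itp,
    place_virtual_sites,
    write_itp,
)

ROUND_TRIP_MOLECULES = [
    ("GLC", "glucose"),
    ("GAL(b1-4)GLC", "lactose"),
    ("GLC(a1-2)FRUF", "sucrose"),
    ("GLC(a1-1)GLC", "trehalose"),
    ("GLC(a1-6)GLC{9}", "dextran9"),
    ("GLC(b1-4)GLC{10}", "cellulose10"),
]


class TestDeriveRingGeometry:
    def _toy(self):
        g = parse_glycan("GAL(b1-4)GLC")
        beads, info = build_beads(g)
        terms = enumerate_bonded_terms(g, info)
        return g, beads, terms

    def test_ring_distances_scaled_by_fifteen_percent(self, rng):
        g, beads, terms = self._toy()
        xyz = rng.normal(size=(20, len(beads), 3))
        lengths = derive_ring_geometry(xyz, terms, beads, ScalingPolicy(ring_scale=1.15))
        raw = derive_ring_geometry(xyz, terms, beads, ScalingPolicy(ring_scale=1.0))
        for t in terms:
            if t.kind != "constraint":
                continue
            assert lengths[t.key()] == pytest.approx(1.15 * raw[t.key()])

    def test_glycosidic_bond_left_unscaled(self, rng):
        g, beads, terms = self._toy()
        xyz = rng.normal(size=(20, len(beads), 3))
        lengths = derive_ring_geometry(xyz, terms, beads, ScalingPolicy(ring_scale=1.15))
        bond = next(t for t in terms if t.kind == "bond")
        i, j = bond.beads
        raw = np.linalg.norm(xyz[:, i - 1] - xyz[:, j - 1], axis=1).mean()
        assert lengths[bond.key()] == pytest.approx(raw)

    def test_mean_point_three_becomes_0_345(self):
        g = parse_glycan("GLC")
        beads, info = build_beads(g)
        terms = enumerate_bonded_terms(g, info)
        # equilateral ring with side 0.3 nm
        s = 0.3
        xyz = np.array([[[0, 0, 0], [s, 0, 0], [s / 2, s * np.sqrt(3) / 2, 0], [0, 0, 0]]])
        lengths = derive_ring_geometry(xyz, terms, beads, ScalingPolicy(), min_frames=1)
        assert all(v == pytest.approx(0.345) for v in lengths.values())


class TestVirtualSites:
    def test_glucose_has_one_equal_weight_site_over_the_ring(self):
        g = parse_glycan("GLC")
        beads, info = build_beads(g)
        (vs,) = place_virtual_sites(g, beads, info)
        assert vs.constituents == (1, 2, 3)
        assert vs.weights == (pytest.approx(1 / 3),) * 3
        assert beads[vs.site - 1].virtual
        assert beads[vs.site - 1].mass == 0.0
        assert beads[vs.site - 1].btype == "TC4"

    def test_disaccharide_has_two_sites(self, lactose_graph):
        beads, info = build_beads(lactose_graph)
        assert len(place_virtual_sites(lactose_graph, beads, info)) == 2

    def test_realized_site_sits_at_the_ring_centroid(self, glucose_index, rng):
        coords = rng.normal(size=(12, 3))
        f = map_coordinates(coords, glucose_index)
        assert np.allclose(f.positions[3], f.positions[:3].mean(axis=0))


class TestEnumerateBondedTerms:
    def counts(self, descriptor):
        g = parse_glycan(descriptor)
        terms = enumerate_bonded_terms(g)
        kinds = {}
        for t in terms:
            kinds[t.kind] = kinds.get(t.kind, 0) + 1
        return kinds

    def test_monosaccharide_is_a_pure_constraint_triangle(self):
        assert self.counts("GLC") == {"constraint": 3}

    def test_disaccharide_terms(self):
        kinds = self.counts("GAL(b1-4)GLC")
        assert kinds["bond"] == 1
        assert kinds.get("angle", 0) + kinds.get("angle_restricted", 0) == 4
        assert kinds["dihedral"] == 1
        assert "dihedral_triad" not in kinds

    def test_linear_trisaccharide_gains_one_triad_dihedral(self):
        kinds = self.counts("GLC(b1-4)GLC{3}")
        assert kinds["dihedral"] == 2
        assert kinds["dihedral_triad"] == 1

    def test_cellulose_50mer_counting(self):
        kinds = self.counts("GLC(b1-4)GLC{50}")
        assert kinds["constraint"] == 150
        assert kinds["bond"] == 49
        assert kinds["dihedral"] == 49
        assert kinds["dihedral_triad"] == 48

    def test_angles_covered_by_a_dihedral_are_restricted(self):
        g = parse_glycan("GAL(b1-4)GLC")
        terms = enumerate_bonded_terms(g)
        covered = set()
        for t in terms:
            if t.kind.startswith("dihedral"):
                b = t.beads
                for tri in (b[:3], b[1:]):
                    covered.add(tri if tri[0] <= tri[-1] else tuple(reversed(tri)))
        for t in terms:
            if t.kind == "angle_restricted":
                assert t.beads in covered
            if t.kind == "angle":
                assert t.beads not in covered


class TestExclusions:
    def bfs_oracle(self, beads, terms, depth):
        graph = nx.Graph()
        graph.add_nodes_from(b.index for b in beads if not b.virtual)
        for t in terms:
            if t.kind in ("constraint", "bond"):
                graph.add_edge(*t.beads)
        pairs = set()
        for i in graph:
            dist = nx.single_source_shortest_path_length(graph, i, cutoff=depth)
            pairs.update((min(i, j), max(i, j)) for j, d in dist.items() if 0 < d <= depth)
        return sorted(pairs)

    @pytest.mark.parametrize("depth", [1, 3])
    def test_dextran_9mer_matches_shortest_path_oracle(self, depth):
        g = parse_glycan("GLC(a1-6)GLC{9}")
        beads, info = build_beads(g)
        terms = enumerate_bonded_terms(g, info)
        got = assign_exclusions(beads, terms, ExclusionPolicy(depth))
        assert got == self.bfs_oracle(beads, terms, depth)

    def test_depth_one_disaccharide_is_exactly_the_bonded_pairs(self, lactose_graph):
        beads, info = build_beads(lactose_graph)
        terms = enumerate_bonded_terms(lactose_graph, info)
        got = set(assign_exclusions(beads, terms, ExclusionPolicy(1)))
        bonded = {tuple(sorted(t.beads)) for t in terms if t.kind in ("constraint", "bond")}
        assert got == bonded

    def test_single_ring_depth_one_is_the_three_constraint_pairs(self):
        g = parse_glycan("GLC")
        beads, info = build_beads(g)
        terms = enumerate_bonded_terms(g, info)
        assert assign_exclusions(beads, terms, ExclusionPolicy(1)) == [(1, 2), (1, 3), (2, 3)]

    def test_virtual_sites_are_excluded_from_their_ring(self):
        g = parse_glycan("GLC")
        beads, info = build_beads(g)
        terms = enumerate_bonded_terms(g, info)
        vsites = place_virtual_sites(g, beads, info)
        got = set(assign_exclusions(beads, terms, ExclusionPolicy(1), vsites))
        assert {(1, 4), (2, 4), (3, 4)} <= got

    def test_default_policy_is_three_for_dextran_one_otherwise(self):
        assert default_exclusion_policy(parse_glycan("GLC(a1-6)GLC{9}")).bonded_neighbor_depth == 3
        assert default_exclusion_policy(parse_glycan("GLC(b1-4)GLC{9}")).bonded_neighbor_depth == 1
        assert default_exclusion_policy(parse_glycan("GAL(b1-4)GLC")).bonded_neighbor_depth == 1


class TestAssemble:
    def test_glucose_three_beads_one_vs_three_constraints_no_angles(self):
        top = build_ideal_topology("GLC")
        assert len(top.beads) == 4
        assert sum(b.virtual for b in top.beads) == 1
        assert len(top.terms_of("constraint")) == 3
        assert top.terms_of("angle", "angle_restricted", "dihedral", "dihedral_triad") == []

    def test_lactose_bond_connects_B_and_A_beads(self, lactose_graph):
        top = build_ideal_topology("GAL(b1-4)GLC", n_frames=50, seed=1)
        (bond,) = top.terms_of("bond")
        named = {top.beads[i - 1].name for i in bond.beads}
        assert named == {"1B", "2A"}

    def test_alpha_and_beta_links_get_distinct_bond_lengths(self):
        truth_a = {"bond": (0.52, 7000.0)}
        truth_b = {"bond": (0.47, 7000.0)}
        from sugarcg.fitting import generate_synthetic_reference
        from sugarcg.pipeline import parametrize

        tops = []
        for d, truth in (("GLC(a1-4)GLC", truth_a), ("GLC(b1-4)GLC", truth_b)):
            g = parse_glycan(d)
            ref = generate_synthetic_reference(g, n_frames=3000, seed=5, ground_truth=truth)
            tops.append(parametrize(g, ref.coords, min_frames=1))
        b_a = tops[0].terms_of("bond")[0].params[0]
        b_b = tops[1].terms_of("bond")[0].params[0]
        assert abs(b_a - b_b) > 0.03

    def test_missing_fitted_parameter_is_reported(self):
        from sugarcg.topology import assemble_topology

        g = parse_glycan("GLC")
        with pytest.raises(MissingParameterError, match="constraint"):
            assemble_topology(g, fitted={})

    def test_glycosidic_bead_types_reflect_the_linkage_group(self):
        top16 = build_ideal_topology("GLC(a1-6)GLC", n_frames=50, seed=1)
        donor_a = next(b for b in top16.beads if b.name == "2A")
        assert donor_a.btype == "SN6r"
        top14 = build_ideal_topology("GLC(a1-4)GLC", n_frames=50, seed=1)
        donor_a = next(b for b in top14.beads if b.name == "2A")
        assert donor_a.btype == "SP1r"

    @pytest.mark.parametrize("descriptor,_", ROUND_TRIP_MOLECULES)
    def test_scaled_ring_triangles_remain_valid(self, descriptor, _):
        # CGTopology.validate() raises on triangle-inequality violations
        build_ideal_topology(descriptor, n_frames=60, seed=2).validate()


class TestItpRoundTrip:
    @pytest.mark.parametrize("descriptor,name", ROUND_TRIP_MOLECULES)
    def test_write_parse_is_byte_consistent(self, descriptor, name):
        top = build_ideal_topology(descriptor, n_frames=60, seed=2, name=name)
        text = write_itp(top)
        reread = parse_itp(text)
        assert reread == top
        assert write_itp(reread) == text

    def test_identical_inputs_give_byte_identical_files(self):
        a = write_itp(build_ideal_topology("GLC(a1-6)GLC{4}", n_frames=60, seed=9))
        b = write_itp(build_ideal_topology("GLC(a1-6)GLC{4}", n_frames=60, seed=9))
        assert a == b

    def test_glucose_file_has_three_constraints_and_one_virtual_site_record(self):
        text = write_itp(build_ideal_topology("GLC"))
        section = None
        counts = {"constraints": 0, "virtual_sitesn": 0}
        for line in text.splitlines():
            s = line.strip()
            if s.startswith("["):
                section = s.strip("[] ")
            elif s and not s.startswith(";") and section in counts:
                counts[section] += 1
        assert counts == {"constraints": 3, "virtual_sitesn": 1}

    def test_dextran_exclusion_section_matches_the_oracle(self):
        g = parse_glycan("GLC(a1-6)GLC{5}")
        top = build_ideal_topology("GLC(a1-6)GLC{5}", n_frames=60, seed=2)
        beads, info = build_beads(g)
        terms = enumerate_bonded_terms(g, info)
        vsites = place_virtual_sites(g, beads, info)
        expected = assign_exclusions(beads, terms, ExclusionPolicy(3), vsites)
        reread = parse_itp(write_itp(top))
        assert sorted(reread.exclusions) == expected
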