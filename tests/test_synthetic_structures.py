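"""Generator contracts: counts, determinism, geometry, component structure."""

import math

import networkx as nx
import numpy as np
import pytest

import phasegraph as pg
from phasegraph.particles import wrap_positions


class TestFCC:
    @pytest.mark.parametrize("cells,expected", [(1, 4), (3, 108), (9, 2916)])
    def test_atom_count(self, cells, expected):
        config = pg.generate_fcc(cells, 0.54)
        assert config.n_sites == expected
        assert config.n_molecules == expected

    def test_nearest_neighbor_distance(self):
        a = 0.54
        config = pg.generate_fcc(3, a)
        delta = pg.minimum_image(
            config.positions[None, :, :] - config.positions[:, None, :], config.box
        )
        dist = np.linalg.norm(delta, axis=-1)
        np.fill_diagonal(dist, np.inf)
        assert dist.min() == pytest.approx(a / math.sqrt(2), rel=1e-9)

    def test_rejects_bad_inputs(self):
        with pytest.raises(pg.ConfigurationError):
            pg.generate_fcc(0, 0.5)
        with pytest.raises(pg.ConfigurationError):
            pg.generate_fcc(3, -1.0)


class TestIdealSolution:
    def test_counts_and_roles(self):
        config = pg.generate_ideal_solution(50, box=(8, 8, 8), seed=3)
        assert config.n_molecules == 50
        assert config.n_sites == 150
        roles = config.site_role[config.molecule_id == config.molecules[0]]
        assert list(roles) == ["head", "tail", "terminal_tail"]

    def test_single_molecule(self):
        config = pg.generate_ideal_solution(1, box=(5, 5, 5), seed=9)
        assert config.n_molecules == 1

    def test_deterministic_under_seed(self):
        a = pg.generate_ideal_solution(30, box=(8, 8, 8), seed=11)
        b = pg.generate_ideal_solution(30, box=(8, 8, 8), seed=11)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_overcrowding_raises(self):
        with pytest.raises(pg.ConfigurationError, match="density"):
            pg.generate_ideal_solution(200, box=(1.5, 1.5, 1.5), seed=0)

    def test_min_separation_between_molecules(self):
        config = pg.generate_ideal_solution(40, box=(8, 8, 8), seed=2)
        delta = pg.minimum_image(
            config.positions[None, :, :] - config.positions[:, None, :], config.box
        )
        dist = np.linalg.norm(delta, axis=-1)
        inter = config.molecule_id[None, :] != config.molecule_id[:, None]
        assert dist[inter].min() >= 0.3


class TestMesophases:
    def test_micellar_components_match_micelle_count(self):
        config = pg.generate_micellar(n_micelles=32, aggregation_number=25, seed=4)
        graph = pg.build_contact_graph(config)
        comps = pg.connected_components(graph)
        assert len(comps) == 32
        assert all(len(c) == 25 for c in comps)

    def test_single_micelle_connected(self):
        config = pg.generate_micellar(n_micelles=1, aggregation_number=20,
                                      box=(12, 12, 12), seed=0)
        graph = pg.build_contact_graph(config)
        assert len(pg.connected_components(graph)) == 1

    def test_aggregation_one_gives_isolated_nodes(self):
        config = pg.generate_micellar(n_micelles=5, aggregation_number=1,
                                      box=(30, 30, 30), seed=0)
        graph = pg.build_contact_graph(config)
        assert graph.number_of_edges() == 0
        assert graph.number_of_nodes() == 5

    def test_hexagonal_components_wrap_z(self):
        config = pg.generate_hexagonal(seed=5)
        assert config.n_molecules == 800
        graph = pg.build_contact_graph(config)
        comps = pg.connected_components(graph)
        assert len(comps) == 4
        # each cylinder wraps through the periodic z boundary: its graph
        # contains a cycle longer than any cross-section loop
        for comp in comps:
            sub = graph.subgraph(comp)
            cycles = nx.cycle_basis(sub.copy())
            assert max(len(c) for c in cycles) >= 10

    def test_hexagonal_single_ring(self):
        config = pg.generate_hexagonal(
            n_cylinders=1, molecules_per_ring=8, rings_per_cylinder=1,
            ring_spacing=2.0, seed=0, jitter=0.0)
        graph = pg.build_contact_graph(config)
        comps = pg.connected_components(graph)
        assert len(comps[0]) == 8

    def test_hexagonal_interior_degree_uniform(self):
        config = pg.generate_hexagonal(seed=6, jitter=0.0)
        graph = pg.build_contact_graph(config)
        degrees = np.array([d for _, d in graph.degree()])
        assert len(np.unique(degrees)) <= 2  # staggered rings alternate slightly

    def test_hexagonal_box_mismatch_raises(self):
        with pytest.raises(pg.ConfigurationError):
            pg.generate_hexagonal(box=(11, 11, 7.0), seed=0)  # box_z != 20*0.5

    def test_lamellar_counts_and_components(self):
        config = pg.generate_lamellar(bridge_count=0, seed=7)
        assert config.n_molecules == 800
        graph = pg.build_contact_graph(config)
        assert len(pg.connected_components(graph)) == 4

    def test_bridges_merge_lamellae(self):
        config = pg.generate_lamellar(bridge_count=1, seed=7)
        graph = pg.build_contact_graph(config)
        assert len(pg.connected_components(graph)) == 1

    def test_holes_reduce_mean_degree(self):
        dense = pg.generate_lamellar(hole_fraction=0.0, seed=8)
        holey = pg.generate_lamellar(hole_fraction=0.1, seed=8)
        deg = lambda cfg: np.mean(  # noqa: E731
            [d for _, d in pg.build_contact_graph(cfg).degree()])
        assert deg(holey) < deg(dense)
        assert holey.n_molecules == 720

    def test_hole_fraction_one_rejected(self):
        with pytest.raises(pg.ConfigurationError):
            pg.generate_lamellar(hole_fraction=1.0, seed=0)

    def test_generators_deterministic(self):
        for gen in (pg.generate_micellar, pg.generate_hexagonal,
                    pg.generate_lamellar):
            a, b = gen(seed=13), gen(seed=13)
            np.testing.assert_array_equal(a.positions, b.positions)

    def test_positions_wrapped_idempotent(self):
        for gen in (pg.generate_micellar, pg.generate_hexagonal,
                    pg.generate_lamellar):
            config = gen(seed=1)
            assert np.all(config.positions >= 0)
            assert np.all(config.positions < config.box)
            rewrapped = wrap_positions(config.positions, config.box)
            np.testing.assert_array_equal(rewrapped, config.positions)


class TestIdealized:
    @pytest.mark.parametrize("kind,n_mol", [
        ("bidimensional_micelle", 8),
        ("infinite_cylinder", 128),
        ("monolayer", 224),
        ("bilayer1", 224),
        ("bilayer2", 448),
    ])
    def test_molecule_counts(self, kind, n_mol):
        assert pg.generate_idealized(kind).n_molecules == n_mol

    def test_bidimensional_micelle_is_planar(self):
        config = pg.generate_idealized("bidimensional_micelle")
        assert np.ptp(config.positions[:, 2]) == pytest.approx(0.0, abs=1e-12)

    def test_infinite_cylinder_connected_single_component(self):
        config = pg.generate_idealized("infinite_cylinder")
        graph = pg.build_contact_graph(config)
        assert len(pg.connected_components(graph)) == 1

    def test_unknown_kind_raises(self):
        with pytest.raises(pg.ConfigurationError):
            pg.generate_idealized("vesicle")


class TestFractalGraph:
    @pytest.mark.parametrize("b,f,expected", [
        (3, 1 / 3, 1.0),
        (6, 1 / 3, math.log(6) / math.log(3)),
        (4, 1 / 2, 2.0),
    ])
    def test_analytic_dimension(self, b, f, expected):
        graph = pg.generate_fractal_graph(b, f, levels=2)
        assert graph.graph["analytic_dimension"] == pytest.approx(expected)

    def test_level_one_exhaustive(self):
        # b=6, f=1/3, one level: a 3-edge backbone path with one dangling
        # edge at each of its three junctions -> 7 nodes, 6 edges, and BFS
        # distances from the origin terminal match a hand enumeration
        graph = pg.generate_fractal_graph(6, 1 / 3, levels=1)
        assert graph.number_of_edges() == 6
        assert graph.number_of_nodes() == 7
        assert sorted(d for _, d in graph.degree()) == [1, 1, 1, 1, 2, 3, 3]
        dist = nx.single_source_shortest_path_length(graph, graph.graph["origin"])
        assert sorted(dist.values()) == [0, 1, 2, 2, 3, 3, 4]
        assert dist[graph.graph["terminal"]] == 3

    def test_edge_count_multiplies_by_b(self):
        for levels in (1, 2, 3):
            graph = pg.generate_fractal_graph(6, 1 / 3, levels)
            assert graph.number_of_edges() == 6 ** levels

    def test_no_self_loops_or_parallel_edges(self):
        graph = pg.generate_fractal_graph(7, 1 / 3, 2)
        assert nx.number_of_selfloops(graph) == 0
        assert graph.number_of_nodes() == len(set(graph.nodes))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(pg.ConfigurationError):
            pg.generate_fractal_graph(3, 0.4, 2)  # 1/f not integer
        with pytest.raises(pg.ConfigurationError):
            pg.generate_fractal_graph(2, 1 / 3, 2)  # dimension < 1
        with pytest.raises(pg.ConfigurationError):
            pg.generate_fractal_graph(3, 1.0, 2)
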