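"""Network construction, invariants and serialization round-trips."""

import math

import numpy as np
import pytest

import vasodyn as v
from vasodyn.network import NetworkError


class TestTaper:
    @pytest.mark.parametrize(
        "depth,expected",
        [(0.0, 18.0), (840.0, 12.6), (250.0, 16.392857142857142)],
    )
    def test_linear_taper_values(self, depth, expected):
        assert v.pa_taper_diameter(depth) == pytest.approx(expected, rel=1e-12)

    def test_strictly_decreasing(self):
        depths = np.linspace(0, 840, 57)
        d = [v.pa_taper_diameter(z) for z in depths]
        assert np.all(np.diff(d) < 0)

    @pytest.mark.parametrize("depth", [-1.0, 840.1])
    def test_domain_errors(self, depth):
        with pytest.raises(NetworkError):
            v.pa_taper_diameter(depth)


class TestGeneration:
    def test_default_counts(self, default_network):
        art = default_network.arteriolar_segments()
        assert len(art) == 1009
        pa = [s for s in art if s.cls == "PA"]
        assert len(pa) == 30 * 28
        assert len(art) - len(pa) == 169

    def test_boundary_nodes(self, default_network):
        assert default_network.abn.boundary_pressure == 60.0
        assert default_network.vbn.boundary_pressure == 10.0

    def test_minimal_network(self):
        cfg = v.NetworkGenConfig(n_PA=1, n_pial_segments=1)
        net = v.generate_default_network(cfg)
        assert len(net.arteriolar_segments()) == 29

    def test_infeasible_topology(self):
        with pytest.raises(NetworkError):
            cfg = v.NetworkGenConfig(n_PA=5, n_pial_segments=3)
            v.generate_default_network(cfg)

    def test_segment_count_identity(self, small_config, small_network):
        art = small_network.arteriolar_segments()
        expected = small_config.n_pial_segments + small_config.n_PA * small_config.segments_per_PA
        assert len(art) == expected

    def test_pa_diameter_monotone_with_depth(self, default_network):
        for k in (0, 17, 29):
            segs = sorted(
                (s for s in default_network.segments.values() if s.id.startswith(f"pa{k}_s")),
                key=lambda s: s.cortical_depth,
            )
            d = [s.diameter for s in segs]
            assert all(a > b for a, b in zip(d, d[1:]))

    def test_contractility_non_increasing_with_depth(self, default_network):
        segs = sorted(
            (s for s in default_network.segments.values() if s.id.startswith("pa0_s")),
            key=lambda s: s.cortical_depth,
        )
        ci = [s.contractility_index for s in segs]
        assert all(a >= b for a, b in zip(ci, ci[1:]))

    def test_wall_thickness_invariant(self, default_network):
        for s in default_network.segments.values():
            assert s.wall_thickness == pytest.approx(0.1 * s.d_active_max, rel=1e-9)

    def test_pa_roots_attach_to_pial(self, default_network):
        adj = default_network.adjacency
        for k in range(30):
            incident = adj[f"pa_root_{k}"]
            classes = {default_network.segments[s].cls for s in incident}
            assert "pial" in classes and "PA" in classes

    def test_deterministic(self):
        a = v.generate_default_network()
        b = v.generate_default_network()
        assert list(a.segments) == list(b.segments)
        assert all(
            a.segments[k].diameter == b.segments[k].diameter for k in a.segments
        )


class TestCouplingGraph:
    def test_linear_chain_neighbors(self):
        from tests.conftest import chain_network

        net = chain_network(3)
        adj = v.arteriolar_coupling_graph(net)
        assert adj["s1"] == {"s0", "s2"}
        assert adj["s0"] == {"s1"}

    def test_pa_root_couples_to_pial_parent(self, default_network):
        adj = v.arteriolar_coupling_graph(default_network)
        neighbors = adj["pa0_s0"]
        classes = {default_network.segments[s].cls for s in neighbors}
        assert "pial" in classes

    def test_excludes_microvessels_and_symmetric(self, default_network):
        adj = v.arteriolar_coupling_graph(default_network)
        for sid, nbrs in adj.items():
            assert default_network.segments[sid].is_arteriolar
            for nb in nbrs:
                assert default_network.segments[nb].is_arteriolar
                assert sid in adj[nb]

    def test_isolated_segment(self):
        from tests.conftest import chain_network

        net = chain_network(1)
        adj = v.arteriolar_coupling_graph(net)
        assert adj["s0"] == set()


class TestSerialization:
    @pytest.mark.parametrize("fmt", ["graphml", "csv"])
    def test_round_trip(self, tmp_path, small_network, fmt):
        path = tmp_path / f"net.{fmt}"
        v.write_network(small_network, path)
        back = v.read_network(path)
        assert set(back.segments) == set(small_network.segments)
        assert set(back.nodes) == set(small_network.nodes)
        for sid, s in small_network.segments.items():
            b = back.segments[sid]
            assert (b.cls, b.node_a, b.node_b, b.is_arteriolar) == (
                s.cls,
                s.node_a,
                s.node_b,
                s.is_arteriolar,
            ) or (b.cls, b.node_b, b.node_a, b.is_arteriolar) == (
                s.cls,
                s.node_a,
                s.node_b,
                s.is_arteriolar,
            )
            for attr in ("length", "diameter", "d_active_max", "wall_thickness",
                         "cortical_depth", "contractility_index"):
                assert getattr(b, attr) == pytest.approx(getattr(s, attr), rel=1e-9)

    def test_csv_missing_column_rejected(self, tmp_path, small_network):
        import pandas as pd

        path = tmp_path / "net.csv"
        v.write_network(small_network, path)
        df = pd.read_csv(path).drop(columns=["h_um"])
        df.to_csv(path, index=False)
        with pytest.raises(NetworkError, match="missing"):
            v.read_network(path)

    def test_two_abn_rejected(self, tmp_path, small_network):
        path = tmp_path / "net.graphml"
        g = small_network.to_networkx()
        g.nodes["pa_root_0"]["kind"] = "artery_boundary"
        g.nodes["pa_root_0"]["boundary_pressure"] = 60.0
        import networkx as nx

        nx.write_graphml(g, path)
        with pytest.raises(NetworkError, match="exactly one"):
            v.read_network(path)
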