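"""Hydraulic network model: resistance formula, solver, concentration
propagation and inverse design."""

import numpy as np
import pytest

from mcdkit import (
    ChannelSegment,
    DesignConstraints,
    DesignEdge,
    NetworkSpec,
    design_network,
    propagate_concentration,
    rect_resistance,
    solve_flow,
)
from mcdkit.errors import (
    InfeasibleConstraintsError,
    InvalidGeometryError,
    UnsolvableNetworkError,
)
from mcdkit.units import MBAR_TO_MPA, ULMIN_TO_UM3_PER_S


class TestRectResistance:
    def test_linear_in_length(self):
        r1 = rect_resistance(5000.0, 300.0, 90.0, 1.0)
        r2 = rect_resistance(10000.0, 300.0, 90.0, 1.0)
        assert r2 == pytest.approx(2.0 * r1, rel=1e-12)

    def test_square_duct_matches_extreme_truncation(self):
        # oracle: the same series summed to two orders of magnitude more terms
        r = rect_resistance(1000.0, 80.0, 80.0, 1.0)
        r_ref = rect_resistance(1000.0, 80.0, 80.0, 1.0, n_max=100001)
        assert r == pytest.approx(r_ref, rel=1e-9)

    def test_wide_channel_approaches_parallel_plates(self):
        L, w, h, mu = 1000.0, 10000.0, 100.0, 1.0
        r = rect_resistance(L, w, h, mu)
        plates = 12.0 * mu * L / (w * h ** 3)
        assert abs(r - plates) / plates < 0.007

    def test_symmetric_in_w_and_h(self):
        assert rect_resistance(1000.0, 300.0, 90.0) == pytest.approx(
            rect_resistance(1000.0, 90.0, 300.0), rel=1e-12)

    @pytest.mark.parametrize("bad", [(-1, 1, 1, 1), (1, 0, 1, 1),
                                     (1, 1, -2, 1), (1, 1, 1, 0)])
    def test_rejects_nonpositive_dimensions(self, bad):
        with pytest.raises(InvalidGeometryError):
            rect_resistance(*bad)


def _plain(eid, L, w=100.0, h=90.0):
    return ChannelSegment(eid, "plain", L, w, h)


class TestSolveFlow:
    def test_single_channel_hagen_poiseuille(self):
        seg = _plain("c", 10000.0)
        spec = NetworkSpec([(seg, "in", "out")], {"in": 100.0, "out": 0.0})
        flow = solve_flow(spec)
        q_expect = 100.0 * MBAR_TO_MPA / seg.R / ULMIN_TO_UM3_PER_S
        assert flow.flows_ulmin["c"] == pytest.approx(q_expect, rel=1e-12)

    def test_parallel_channels_split_inversely_to_resistance(self):
        a, b = _plain("a", 5000.0), _plain("b", 20000.0)
        spec = NetworkSpec([(a, "in", "out"), (b, "in", "out")],
                           {"in": 50.0, "out": 0.0})
        flow = solve_flow(spec)
        ratio = flow.flows_ulmin["a"] / flow.flows_ulmin["b"]
        assert ratio == pytest.approx(b.R / a.R, rel=1e-9)

    def test_pressure_scaling_scales_flows_linearly(self):
        segs = [(_plain("a", 8000.0), "in", "m"), (_plain("b", 4000.0), "m", "out"),
                (_plain("c", 6000.0), "m", "out")]
        f1 = solve_flow(NetworkSpec(segs, {"in": 80.0, "out": 0.0}))
        f2 = solve_flow(NetworkSpec(segs, {"in": 240.0, "out": 0.0}))
        for k in f1.flows_ulmin:
            assert f2.flows_ulmin[k] == pytest.approx(3.0 * f1.flows_ulmin[k],
                                                      rel=1e-12)

    def test_mass_conserved_at_internal_nodes(self, mcd_flow):
        boundary = set(mcd_flow.spec.boundaries)
        for node, res in mcd_flow.residuals_ulmin.items():
            if node in boundary:
                continue
            incident = sum(abs(mcd_flow.flows_ulmin[s.id])
                           for s, u, v in mcd_flow.spec.edges
                           if node in (u, v))
            assert abs(res) < 1e-10 * incident

    def test_edges_satisfy_hagen_poiseuille(self, mcd_flow):
        p = mcd_flow.pressures_mbar
        for seg, u, v in mcd_flow.spec.edges:
            dp = (p[u] - p[v]) * MBAR_TO_MPA
            q = mcd_flow.flows_ulmin[seg.id] * ULMIN_TO_UM3_PER_S
            assert dp == pytest.approx(q * seg.R, rel=1e-9)

    def test_disconnected_boundary_component_rejected(self):
        spec = NetworkSpec([(_plain("a", 1000.0), "in", "out"),
                            (_plain("b", 1000.0), "x", "y")],
                           {"in": 10.0, "out": 0.0})
        with pytest.raises(UnsolvableNetworkError):
            solve_flow(spec)

    def test_random_ladder_networks_match_series_parallel_reduction(self):
        # oracle: closed-form series/parallel reduction of the same ladder
        rng = np.random.default_rng(42)
        for _ in range(20):
            n_rungs = rng.integers(1, 5)
            edges, r_segments = [], []
            node = "n0"
            r_total = 0.0
            for i in range(n_rungs):
                nxt = f"n{i + 1}"
                k = rng.integers(1, 3)  # 1 = series element, 2 = parallel pair
                rs = []
                for j in range(k):
                    L = float(rng.uniform(1000.0, 30000.0))
                    seg = _plain(f"e{i}_{j}", L)
                    edges.append((seg, node, nxt))
                    rs.append(seg.R)
                r_total += 1.0 / sum(1.0 / r for r in rs)
                node = nxt
            p_in = float(rng.uniform(10.0, 200.0))
            spec = NetworkSpec(edges, {"n0": p_in, node: 0.0})
            flow = solve_flow(spec)
            q_total = sum(flow.flows_ulmin[s.id] for s, u, v in spec.edges
                          if u == "n0")
            q_expect = p_in * MBAR_TO_MPA / r_total / ULMIN_TO_UM3_PER_S
            assert q_total == pytest.approx(q_expect, rel=1e-9)


class TestPropagateConcentration:
    def _merge(self, flows_conc):
        """Build a star merge with given (Q, C) inlets; returns outlet conc."""
        edges, bnd, conc = [], {"out": 0.0}, {}
        # realise each inlet flow with a resistance giving that Q at 10 mbar drop
        for i, (q, c) in enumerate(flows_conc):
            r = 10.0 * MBAR_TO_MPA / (q * ULMIN_TO_UM3_PER_S)
            edges.append((ChannelSegment(f"in{i}", "fixed-resistance", R=r),
                          f"s{i}", "m"))
            bnd[f"s{i}"] = 20.0
            conc[f"s{i}"] = c
        q_tot = sum(q for q, _ in flows_conc)
        r_out = 10.0 * MBAR_TO_MPA / (q_tot * ULMIN_TO_UM3_PER_S)
        edges.append((ChannelSegment("o", "fixed-resistance", R=r_out),
                      "m", "out"))
        flow = solve_flow(NetworkSpec(edges, bnd, conc))
        return propagate_concentration(flow)["o"]

    def test_one_to_nine_merge_dilutes_tenfold(self):
        assert self._merge([(1.0, 0.8), (9.0, 0.0)]) == pytest.approx(
            0.08, rel=1e-9)

    def test_identical_streams_unchanged(self):
        assert self._merge([(3.0, 0.6), (7.0, 0.6)]) == pytest.approx(
            0.6, rel=1e-12)

    def test_three_way_flow_weighted_mean(self):
        got = self._merge([(2.0, 1.0), (3.0, 0.5), (5.0, 0.0)])
        assert got == pytest.approx(0.35, rel=1e-9)


class TestDesignNetwork:
    def test_single_edge_inversion_roundtrip(self):
        cons = DesignConstraints(
            [DesignEdge("c", "in", "out", 10.0, w_um=100.0, h_um=90.0)],
            {"in": 50.0, "out": 0.0})
        spec = design_network(cons)
        seg = spec.edges[0][0]
        assert seg.R == pytest.approx(
            50.0 * MBAR_TO_MPA / (10.0 * ULMIN_TO_UM3_PER_S), rel=1e-9)
        flow = solve_flow(spec)
        assert flow.flows_ulmin["c"] == pytest.approx(10.0, rel=1e-9)

    def test_y_junction_resistance_ratio(self):
        cons = DesignConstraints(
            [DesignEdge("r1", "n", "out", 1.0, w_um=100.0, h_um=90.0),
             DesignEdge("r2", "n", "out", 9.0, w_um=100.0, h_um=90.0)],
            {"n": 30.0, "out": 0.0})
        spec = design_network(cons)
        segs = {s.id: s for s, _, _ in spec.edges}
        assert segs["r1"].R / segs["r2"].R == pytest.approx(9.0, rel=1e-12)

    def test_mass_inconsistent_targets_rejected(self):
        cons = DesignConstraints(
            [DesignEdge("a", "in", "m", 5.0, w_um=100.0, h_um=90.0),
             DesignEdge("b", "m", "out", 4.0, w_um=100.0, h_um=90.0)],
            {"in": 50.0, "out": 0.0})
        with pytest.raises(InfeasibleConstraintsError):
            design_network(cons)

    def test_design_then_solve_recovers_all_target_flows(
            self, mcd_flow, mcd_constraints):
        for e in mcd_constraints.edges:
            assert mcd_flow.flows_ulmin[e.id] == pytest.approx(
                e.Q_ulmin, rel=1e-6)

    def test_network_spec_json_roundtrip(self, mcd_flow):
        spec = mcd_flow.spec
        restored = NetworkSpec.from_json(spec.to_json())
        f2 = solve_flow(restored)
        for k, q in mcd_flow.flows_ulmin.items():
            assert f2.flows_ulmin[k] == pytest.approx(q, rel=1e-9)


class TestDilutionChain:
    def test_serial_dilution_is_logarithmic(self, mcd_flow):
        from mcdkit import mcd_dilution_profile
        prof = mcd_dilution_profile(mcd_flow)
        for i in range(5):
            assert prof[i] == pytest.approx(10.0 ** -i, rel=1e-9)
        assert prof[5] == 0.0

    def test_run_pressures_give_same_dilution(self):
        from mcdkit import mcd_dilution_profile, solve_mcd
        prof = mcd_dilution_profile(solve_mcd(200.0, 140.0))
        for i in range(5):
            assert prof[i] == pytest.approx(10.0 ** -i, rel=1e-9)
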