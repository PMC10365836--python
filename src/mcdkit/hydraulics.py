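"""Hydraulic circuit model of pressure-driven laminar microchannel networks.

For incompressible laminar flow in a constant cross-section channel the
pressure drop obeys the Hagen--Poiseuille law, Δp = Q·R, with R the hydraulic
resistance set by the fluid viscosity and channel geometry.  Combining this
with mass conservation at junctions (Σ Q_i = 0) turns a microfluidic network
into a linear "circuit" problem: node pressures solve a weighted graph
Laplacian with Dirichlet boundary pressures, exactly as node voltages do in a
resistor network.

This module provides:

* :func:`rect_resistance` -- the exact series solution for a rectangular duct;
* :class:`NetworkSpec` / :func:`solve_flow` -- forward solution of a network;
* :func:`propagate_concentration` -- flow-weighted solute bookkeeping through
  merges (streams assumed fully mixed at junction outlets);
* :func:`design_network` -- the inverse problem: given boundary pressures,
  a set of fixed resistances and a complete, mass-consistent assignment of
  target flows, find the resistances (and hence channel lengths) of the
  remaining edges.

Units at the interface are bench units (μm, mPa·s, mbar, μl·min⁻¹,
mPa·s·μm⁻³); see :mod:`mcdkit.units`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import (
    DegenerateNetworkError,
    InfeasibleConstraintsError,
    InfeasiblePressuresError,
    InvalidGeometryError,
    RecirculationError,
    UnsolvableNetworkError,
)
from .units import MBAR_TO_MPA, ULMIN_TO_UM3_PER_S

__all__ = [
    "rect_resistance",
    "ChannelSegment",
    "NetworkSpec",
    "FlowSolution",
    "DilutionProfile",
    "DesignEdge",
    "DesignConstraints",
    "solve_flow",
    "propagate_concentration",
    "design_network",
]

#: default water viscosity at 20 °C, mPa·s
WATER_VISCOSITY = 1.0

#: odd-term truncation of the rectangular-duct series; relative error < 1e-12
#: for aspect ratios w/h >= 1 (the swap below enforces that regime) at
#: negligible cost (the series is evaluated vectorised).
_SERIES_TERMS = 1001


def rect_resistance(L: float, w: float, h: float, mu: float = WATER_VISCOSITY,
                    n_max: int = _SERIES_TERMS) -> float:
    """Hydraulic resistance of a rectangular duct, mPa·s·μm⁻³.

    Exact series solution for fully developed laminar flow in a rectangular
    cross-section::

        R = [12 μ L / (w h³)] · [1 − (192 h)/(π⁵ w) Σ_{n odd} tanh(nπw/2h)/n⁵]⁻¹

    evaluated with w ≥ h (the result is symmetric under swapping w and h, and
    the series converges fastest in that regime).

    Parameters are channel length ``L``, width ``w``, height ``h`` (μm) and
    dynamic viscosity ``mu`` (mPa·s).  ``n_max`` truncates the odd-``n``
    series and exists mainly so tests can compare against an extreme
    truncation of the same expression.
    """
    if L <= 0 or w <= 0 or h <= 0 or mu <= 0:
        raise InvalidGeometryError(
            f"channel dimensions and viscosity must be positive "
            f"(L={L}, w={w}, h={h}, mu={mu})")
    if w < h:
        w, h = h, w
    n = np.arange(1, n_max + 1, 2, dtype=float)
    series = float(np.sum(np.tanh(n * math.pi * w / (2.0 * h)) / n ** 5))
    correction = 1.0 - (192.0 * h) / (math.pi ** 5 * w) * series
    return 12.0 * mu * L / (w * h ** 3) / correction


@dataclass(frozen=True)
class ChannelSegment:
    """One edge of the network: a channel with a hydraulic resistance.

    ``kind`` is ``"plain"`` (R computed from rectangular geometry),
    ``"mixer"`` (herringbone micromixer; R measured/supplied) or
    ``"fixed-resistance"`` (R supplied directly).
    """

    id: str
    kind: str = "plain"
    L_um: float | None = None
    w_um: float | None = None
    h_um: float | None = None
    mu_mPa_s: float = WATER_VISCOSITY
    R: float | None = None  # mPa·s·μm⁻³

    def __post_init__(self):
        if self.kind == "plain":
            if self.L_um is None or self.w_um is None or self.h_um is None:
                raise InvalidGeometryError(
                    f"plain segment {self.id!r} needs L, w, h")
            r = rect_resistance(self.L_um, self.w_um, self.h_um, self.mu_mPa_s)
            if self.R is None:
                object.__setattr__(self, "R", r)
            elif abs(self.R - r) > 1e-9 * r:
                raise InvalidGeometryError(
                    f"segment {self.id!r}: supplied R={self.R} inconsistent "
                    f"with geometry (expected {r})")
        elif self.kind in ("mixer", "fixed-resistance"):
            if self.R is None or self.R <= 0:
                raise InvalidGeometryError(
                    f"{self.kind} segment {self.id!r} needs a positive R")
        else:
            raise InvalidGeometryError(f"unknown segment kind {self.kind!r}")
        if self.R is None or self.R <= 0:
            raise InvalidGeometryError(f"segment {self.id!r}: R must be > 0")


@dataclass
class NetworkSpec:
    """A channel network: edges, Dirichlet boundary pressures (mbar) and
    inlet solute concentrations (fractions of the stock concentration C0)."""

    edges: list[tuple[ChannelSegment, str, str]]
    boundaries: dict[str, float]
    inlet_conc: dict[str, float] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        out = set()
        for _, u, v in self.edges:
            out.add(u)
            out.add(v)
        return out

    def graph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for seg, u, v in self.edges:
            g.add_edge(u, v, key=seg.id, segment=seg)
        return g

    def validate(self) -> None:
        nodes = self.nodes
        if not self.boundaries:
            raise UnsolvableNetworkError("at least one boundary node required")
        for n in self.boundaries:
            if n not in nodes:
                raise UnsolvableNetworkError(f"boundary node {n!r} not in network")
        for c in (self.inlet_conc or {}).values():
            if not 0.0 <= c <= 1.0:
                raise ValueError("inlet concentrations must lie in [0, 1]")
        g = self.graph()
        for comp in nx.connected_components(g):
            if not comp & set(self.boundaries):
                raise UnsolvableNetworkError(
                    f"component {sorted(comp)[:4]}... has no boundary pressure")

    # -- JSON round trip -------------------------------------------------
    def to_json(self) -> str:
        edges = []
        for seg, u, v in self.edges:
            d = {"id": seg.id, "from": u, "to": v, "kind": seg.kind}
            if seg.kind == "plain":
                d.update(L_um=seg.L_um, w_um=seg.w_um, h_um=seg.h_um,
                         mu_mPa_s=seg.mu_mPa_s)
            else:
                d["R_mPa_s_per_um3"] = seg.R
            edges.append(d)
        return json.dumps({
            "nodes": sorted(self.nodes),
            "edges": edges,
            "boundaries": self.boundaries,
            "inlet_conc": self.inlet_conc,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        doc = json.loads(text)
        edges = []
        for e in doc["edges"]:
            kind = e.get("kind", "plain")
            if kind == "plain":
                seg = ChannelSegment(e["id"], "plain", e["L_um"], e["w_um"],
                                     e["h_um"], e.get("mu_mPa_s", WATER_VISCOSITY))
            else:
                seg = ChannelSegment(e["id"], kind, R=e["R_mPa_s_per_um3"])
            edges.append((seg, e["from"], e["to"]))
        return cls(edges, dict(doc["boundaries"]), dict(doc.get("inlet_conc", {})))


@dataclass
class FlowSolution:
    """Solved network state.

    ``pressures_mbar`` maps node → pressure; ``flows_ulmin`` maps edge id →
    signed flow (positive from→to); ``residuals_ulmin`` maps node → net flow
    imbalance (≈0 at internal nodes); ``edge_conc`` maps edge id → solute
    fraction of C0 once :func:`propagate_concentration` has run.
    """

    spec: NetworkSpec
    pressures_mbar: dict[str, float]
    flows_ulmin: dict[str, float]
    residuals_ulmin: dict[str, float]
    edge_conc: dict[str, float] = field(default_factory=dict)


@dataclass
class DilutionProfile:
    """Per-observation-channel chemostimulus concentration, as Ci/C0."""

    fractions: list[float]

    def __post_init__(self):
        f = self.fractions
        for a, b in zip(f, f[1:]):
            if b > a + 1e-12:
                raise ValueError("dilution profile must be non-increasing")

    def __iter__(self):
        return iter(self.fractions)

    def __len__(self):
        return len(self.fractions)

    def __getitem__(self, i):
        return self.fractions[i]


def solve_flow(spec: NetworkSpec) -> FlowSolution:
    """Solve node pressures and edge flows for a network.

    Pressures solve the conductance-weighted graph Laplacian with Dirichlet
    boundary pressures; flows follow from Q = Δp/R per edge.
    """
    spec.validate()
    nodes = sorted(spec.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    lap = np.zeros((n, n))
    for seg, u, v in spec.edges:
        g = 1.0 / seg.R
        i, j = idx[u], idx[v]
        lap[i, i] += g
        lap[j, j] += g
        lap[i, j] -= g
        lap[j, i] -= g

    fixed = np.array([nd in spec.boundaries for nd in nodes])
    p = np.zeros(n)
    for nd, val in spec.boundaries.items():
        p[idx[nd]] = val * MBAR_TO_MPA

    free = ~fixed
    if free.any():
        a = lap[np.ix_(free, free)]
        b = -lap[np.ix_(free, fixed)] @ p[fixed]
        try:
            p[free] = np.linalg.solve(a, b)
        except np.linalg.LinAlgError as exc:
            raise DegenerateNetworkError("singular nodal system") from exc

    flows = {}
    residual = np.zeros(n)
    for seg, u, v in spec.edges:
        q = (p[idx[u]] - p[idx[v]]) / seg.R  # μm³/s, positive u→v
        flows[seg.id] = q / ULMIN_TO_UM3_PER_S
        residual[idx[u]] -= q
        residual[idx[v]] += q

    pressures = {nd: p[idx[nd]] / MBAR_TO_MPA for nd in nodes}
    residuals = {nd: residual[idx[nd]] / ULMIN_TO_UM3_PER_S for nd in nodes}
    return FlowSolution(spec, pressures, flows, residuals)


def propagate_concentration(flow: FlowSolution,
                            inlet_conc: dict[str, float] | None = None,
                            ) -> dict[str, float]:
    """Propagate solute concentrations through the solved network.

    At every junction the streams are assumed fully mixed, so each node's
    outgoing concentration is the flow-weighted mean of its inflows,
    Σ(Q_in·C_in)/ΣQ_in, evaluated in topological order of the flow-directed
    graph.  Boundary nodes that feed the network but have no entry in
    ``inlet_conc`` carry solute-free buffer (C = 0).

    Returns edge id → concentration (fraction of C0) and stores the same map
    on ``flow.edge_conc``.
    """
    if inlet_conc is None:
        inlet_conc = flow.spec.inlet_conc or {}
    qmax = max((abs(q) for q in flow.flows_ulmin.values()), default=0.0)
    tol = 1e-12 * max(qmax, 1.0)

    dg = nx.MultiDiGraph()
    dg.add_nodes_from(flow.spec.nodes)
    for seg, u, v in flow.spec.edges:
        q = flow.flows_ulmin[seg.id]
        if abs(q) <= tol:
            continue
        if q > 0:
            dg.add_edge(u, v, key=seg.id, q=q)
        else:
            dg.add_edge(v, u, key=seg.id, q=-q)

    try:
        order = list(nx.topological_sort(dg))
    except nx.NetworkXUnfeasible as exc:
        raise RecirculationError("flow-directed graph contains a cycle") from exc

    node_conc: dict[str, float] = {}
    for nd in order:
        if dg.in_degree(nd) == 0:
            node_conc[nd] = float(inlet_conc.get(nd, 0.0))
        else:
            qtot = 0.0
            qc = 0.0
            for u, _, data in dg.in_edges(nd, data=True):
                qtot += data["q"]
                qc += data["q"] * node_conc[u]
            node_conc[nd] = qc / qtot

    edge_conc = {}
    for u, v, key in dg.edges(keys=True):
        edge_conc[key] = node_conc[u]
    for seg, u, v in flow.spec.edges:  # stagnant edges carry no stream
        edge_conc.setdefault(seg.id, 0.0)
    flow.edge_conc = edge_conc
    return edge_conc


# ---------------------------------------------------------------------------
# Inverse design
# ---------------------------------------------------------------------------

@dataclass
class DesignEdge:
    """One edge of a design constraint set.

    Oriented along the target flow (``Q_ulmin`` > 0 from ``src`` to ``dst``).
    An edge is *fixed* if its resistance is known in advance -- either
    supplied directly (``R``, for mixers and other pre-characterised parts)
    or implied by a complete geometry (``L_um`` with ``w_um``/``h_um``).
    Otherwise it is *free*: the designer chooses its resistance, realised as
    a channel length at the given cross-section (``w_um``, ``h_um``).
    """

    id: str
    src: str
    dst: str
    Q_ulmin: float
    kind: str = "plain"
    R: float | None = None
    L_um: float | None = None
    w_um: float | None = None
    h_um: float | None = None
    mu_mPa_s: float = WATER_VISCOSITY

    @property
    def is_fixed(self) -> bool:
        return self.R is not None or self.L_um is not None

    def fixed_resistance(self) -> float:
        if self.R is not None:
            return self.R
        return rect_resistance(self.L_um, self.w_um, self.h_um, self.mu_mPa_s)


@dataclass
class DesignConstraints:
    """Boundary pressures (mbar), per-edge target flows, and fixed parts."""

    edges: list[DesignEdge]
    boundaries: dict[str, float]
    inlet_conc: dict[str, float] = field(default_factory=dict)


def _check_mass_consistency(cons: DesignConstraints) -> None:
    net: dict[str, float] = {}
    scale: dict[str, float] = {}
    for e in cons.edges:
        if e.Q_ulmin <= 0:
            raise InfeasibleConstraintsError(
                f"edge {e.id!r}: target flow must be positive along src→dst")
        net[e.src] = net.get(e.src, 0.0) - e.Q_ulmin
        net[e.dst] = net.get(e.dst, 0.0) + e.Q_ulmin
        for nd in (e.src, e.dst):
            scale[nd] = scale.get(nd, 0.0) + e.Q_ulmin
    for nd, imbalance in net.items():
        if nd in cons.boundaries:
            continue
        if abs(imbalance) > 1e-9 * scale[nd]:
            raise InfeasibleConstraintsError(
                f"target flows violate mass conservation at node {nd!r} "
                f"(net {imbalance:g} μl/min)")


def design_network(cons: DesignConstraints) -> NetworkSpec:
    """Size the free channels of a network so target flows are realised.

    The fixed-R edges pin pressure *differences*; boundary nodes pin absolute
    pressures.  Groups of nodes connected by fixed edges therefore form rigid
    "clusters" whose internal pressure offsets are known.  Clusters touching a
    boundary are fully determined.  The remaining cluster pressures are
    assigned deterministically by traversing the flow-directed cluster graph
    in topological order: each cluster is placed by linearly interpolating
    pressure along its most constraining flow path -- the downstream route to
    a determined pressure that admits the smallest uniform per-edge drop
    (fixed-edge drops along the route are subtracted from the budget first).
    Taking the smallest drop guarantees no downstream branch is left with a
    negative pressure budget.  Each free edge then gets R = Δp/Q and a
    channel length at its configured cross-section.  Forward-solving the
    result reproduces the target flows to numerical precision.
    """
    _check_mass_consistency(cons)

    nodes = sorted({n for e in cons.edges for n in (e.src, e.dst)})
    for nd in cons.boundaries:
        if nd not in nodes:
            raise InfeasibleConstraintsError(f"boundary node {nd!r} unused")

    # Rigid clusters over fixed edges, with pressure offsets (mPa).
    g_fixed = nx.Graph()
    g_fixed.add_nodes_from(nodes)
    for e in cons.edges:
        if e.is_fixed:
            drop = e.Q_ulmin * ULMIN_TO_UM3_PER_S * e.fixed_resistance()
            g_fixed.add_edge(e.src, e.dst, drop=drop, src=e.src)

    cluster_of: dict[str, int] = {}
    offset: dict[str, float] = {}
    clusters: list[list[str]] = []
    for comp in sorted(nx.connected_components(g_fixed), key=lambda c: sorted(c)[0]):
        cid = len(clusters)
        members = sorted(comp)
        clusters.append(members)
        root = members[0]
        offset[root] = 0.0
        cluster_of[root] = cid
        for u, v in nx.bfs_edges(g_fixed, root):
            data = g_fixed.edges[u, v]
            sgn = -1.0 if data["src"] == u else 1.0  # p(dst) = p(src) - drop
            offset[v] = offset[u] + sgn * data["drop"]
            cluster_of[v] = cid

    # Determined cluster root pressures from boundary nodes.
    root_p: dict[int, float] = {}
    for nd, p_mbar in cons.boundaries.items():
        cid = cluster_of[nd]
        r = p_mbar * MBAR_TO_MPA - offset[nd]
        if cid in root_p and abs(root_p[cid] - r) > 1e-6 * max(1.0, abs(r)):
            raise InfeasibleConstraintsError(
                f"fixed edges wire boundary node {nd!r} inconsistently")
        root_p[cid] = r

    free_edges = [e for e in cons.edges if not e.is_fixed]
    free_cids = {cid for cid in range(len(clusters)) if cid not in root_p}

    if free_cids:
        # flow-directed cluster DAG over free edges
        cg = nx.DiGraph()
        cg.add_nodes_from(range(len(clusters)))
        for e in free_edges:
            cu, cv = cluster_of[e.src], cluster_of[e.dst]
            if cu != cv:
                cg.add_edge(cu, cv)
        try:
            topo = list(nx.topological_sort(cg))
        except nx.NetworkXUnfeasible as exc:
            raise RecirculationError("free-edge cluster graph has a cycle") from exc

        p_vals = [p * MBAR_TO_MPA for p in cons.boundaries.values()]
        fallback_drop = (max(p_vals) - min(p_vals)) / (len(topo) + 1) \
            if max(p_vals) > min(p_vals) else max(abs(v) for v in p_vals) or 1.0

        # Downstream path summaries per free cluster: (k, A, b) means a route
        # leaving member node b crosses k free edges and reaches a determined
        # pressure such that a uniform per-free-edge drop s satisfies
        # p(b) - A = k*s  (fixed-edge drops are folded into A).
        out_edges: dict[str, list[DesignEdge]] = {}
        for e in free_edges:
            out_edges.setdefault(e.src, []).append(e)

        summaries: dict[int, list[tuple[int, float, str]]] = {}
        for cid in reversed(topo):
            if cid not in free_cids:
                continue
            entries: dict[tuple[str, int], float] = {}
            for b in clusters[cid]:
                for e in out_edges.get(b, []):
                    c2 = cluster_of[e.dst]
                    if c2 in root_p:
                        a_val = root_p[c2] + offset[e.dst]
                        key = (b, 1)
                        entries[key] = max(entries.get(key, -np.inf), a_val)
                    else:
                        for k2, a2, b2 in summaries.get(c2, []):
                            a_val = a2 - (offset[b2] - offset[e.dst])
                            key = (b, k2 + 1)
                            entries[key] = max(entries.get(key, -np.inf), a_val)
            summaries[cid] = sorted((k, a, b) for (b, k), a in entries.items())

        for cid in topo:
            if cid not in free_cids:
                continue
            candidates = []
            for e in free_edges:
                if cluster_of[e.dst] != cid or cluster_of[e.src] not in root_p:
                    continue
                p_e = root_p[cluster_of[e.src]] + offset[e.src]
                o_a = offset[e.dst]
                steps = [(p_e + offset[b] - o_a - a_val) / (k + 1)
                         for k, a_val, b in summaries.get(cid, [])]
                s = min(steps) if steps else fallback_drop
                if s <= 0:
                    raise InfeasiblePressuresError(
                        f"no positive pressure budget entering cluster of node "
                        f"{e.dst!r} via edge {e.id!r}")
                candidates.append(p_e - s - o_a)
            if not candidates:
                raise DegenerateNetworkError(
                    f"cluster of nodes {clusters[cid]} has no determined "
                    f"upstream pressure")
            root_p[cid] = min(candidates)

    pressure = {nd: root_p[cluster_of[nd]] + offset[nd] for nd in nodes}

    # Realise free edges; verify feasibility.
    pscale = max(abs(p) for p in pressure.values()) or 1.0
    segments: list[tuple[ChannelSegment, str, str]] = []
    for e in cons.edges:
        drop = pressure[e.src] - pressure[e.dst]
        if e.is_fixed:
            if e.L_um is not None:
                seg = ChannelSegment(e.id, "plain", e.L_um, e.w_um, e.h_um,
                                     e.mu_mPa_s)
            else:
                kind = e.kind if e.kind in ("mixer", "fixed-resistance") \
                    else "fixed-resistance"
                seg = ChannelSegment(e.id, kind, R=e.R)
        else:
            if drop <= 1e-9 * pscale:
                raise InfeasiblePressuresError(
                    f"edge {e.id!r} would need non-positive resistance "
                    f"(Δp = {drop / MBAR_TO_MPA:g} mbar)")
            r_needed = drop / (e.Q_ulmin * ULMIN_TO_UM3_PER_S)
            if e.w_um is not None and e.h_um is not None:
                r_unit = rect_resistance(1.0, e.w_um, e.h_um, e.mu_mPa_s)
                seg = ChannelSegment(e.id, "plain", r_needed / r_unit,
                                     e.w_um, e.h_um, e.mu_mPa_s)
            else:
                seg = ChannelSegment(e.id, "fixed-resistance", R=r_needed)
        segments.append((seg, e.src, e.dst))

    return NetworkSpec(segments, dict(cons.boundaries), dict(cons.inlet_conc))
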