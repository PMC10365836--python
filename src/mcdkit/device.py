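"""Reference design of the multiplexed chemotaxis device (MCD) network.

The device serially dilutes a chemostimulus stock (concentration C0) through
four 1:9 chemostimulus:buffer merges, each followed by a herringbone
micromixer, producing streams at Ci = 10⁻ⁱ·C0 for i = 0..4 plus a
buffer-only control (C5 = 0).  Each of the six streams feeds an observation
channel (1 mm × 90 μm) where it is co-flowed with a central cell band and a
sheathing buffer stream at 20 : 5 : 20 μl·min⁻¹ (the 4:1:4 width
stratification), before a common atmospheric-pressure outlet.

Design constraints used here:

* dilution-layer inlets at 100 mbar, cell-injection inlets at 50 mbar,
  outlet at 0 (1 mbar = 100 Pa); run pressures of 200/140 mbar are accepted
  as an alternative configuration;
* micromixer resistance R_M = 0.0043 mPa·s·μm⁻³ (empirically characterised
  part, used as a given constant);
* per-channel stream rates 20/5/20 μl·min⁻¹.

The mixer throughputs follow from exact mass balance: the last stage only
exports its 20 μl·min⁻¹ observation stream, so walking back up the cascade
gives mixer flows 20, 22, 22.2 and 22.22 μl·min⁻¹ (nominal design value
22 μl·min⁻¹) and a chemical-inlet demand of 22.2̅ μl·min⁻¹.

The exact channel-by-channel geometry of the fabricated chip is not
reproduced here; the network is regenerated from the constraints above by
:func:`mcdkit.hydraulics.design_network`.
"""

from __future__ import annotations

from .hydraulics import (
    DesignConstraints,
    DesignEdge,
    DilutionProfile,
    FlowSolution,
    NetworkSpec,
    design_network,
    propagate_concentration,
    solve_flow,
)

__all__ = [
    "MIXER_RESISTANCE",
    "N_CHANNELS",
    "mcd_constraints",
    "design_mcd",
    "mcd_dilution_profile",
    "observation_feed_edges",
]

#: herringbone micromixer hydraulic resistance, mPa·s·μm⁻³
MIXER_RESISTANCE = 0.0043

#: observation channels (five dilutions + control)
N_CHANNELS = 6

#: chemostimulus / cell / buffer stream rates in each observation channel, μl·min⁻¹
STREAM_RATES = (20.0, 5.0, 20.0)

#: observation-channel cross-section, μm
OBS_WIDTH = 1000.0
OBS_HEIGHT = 90.0
OBS_LENGTH = 20000.0

#: cross-section used when realising designed dilution-layer channels, μm
DESIGN_WIDTH = 100.0
DESIGN_HEIGHT = 90.0

#: cell-injection layer height and inter-layer bridge geometry, μm
CIL_HEIGHT = 71.0
BRIDGE_LENGTH = 500.0
BRIDGE_WIDTH = 200.0


def _mixer_chain():
    """Chemostimulus feed into each mixer, walking back from the last stage."""
    q = [0.0] * 5  # q[i]: chem flow into mixer i (1-based, q[0] unused)
    nxt = 0.0
    for i in range(4, 0, -1):
        q[i] = (STREAM_RATES[0] + nxt) / 10.0
        nxt = q[i]
    return q


def mcd_constraints(p_dilution_mbar: float = 100.0,
                    p_cell_mbar: float = 50.0) -> DesignConstraints:
    """Design constraint set for the MCD network.

    ``p_dilution_mbar`` drives the chemical and buffer inlets of the dilution
    layer; ``p_cell_mbar`` the cell and sheath-buffer inlets of the cell
    injection layer.  Defaults are the design pressures (100/50 mbar); the
    run pressures (200/140 mbar) are a valid alternative.
    """
    q_feed, q_cell, q_sheath = STREAM_RATES
    q = _mixer_chain()
    edges: list[DesignEdge] = []

    def free(eid, src, dst, qq, w=DESIGN_WIDTH, h=DESIGN_HEIGHT):
        edges.append(DesignEdge(eid, src, dst, qq, w_um=w, h_um=h))

    # dilution layer: chem inlet -> stage 0, then the serial-dilution cascade
    free("chem_supply", "chem_in", "d0", q_feed + q[1])
    for i in range(1, 5):
        free(f"to_mixer_{i}", f"d{i - 1}", f"m{i}_in", q[i])
        free(f"buffer_mixer_{i}", "buf_in", f"m{i}_in", 9.0 * q[i])
        edges.append(DesignEdge(f"mixer_{i}", f"m{i}_in", f"d{i}",
                                10.0 * q[i], kind="mixer", R=MIXER_RESISTANCE))
    for i in range(5):
        free(f"feed_{i}", f"d{i}", f"obs{i}", q_feed)
    free("feed_5", "buf_in", "obs5", q_feed)  # control branch, C = 0

    # cell injection layer: designed supply channel + fixed inter-layer bridge
    for i in range(N_CHANNELS):
        free(f"cell_supply_{i}", "cell_in", f"cb{i}", q_cell,
             h=CIL_HEIGHT)
        edges.append(DesignEdge(f"cell_bridge_{i}", f"cb{i}", f"obs{i}", q_cell,
                                L_um=BRIDGE_LENGTH, w_um=BRIDGE_WIDTH,
                                h_um=CIL_HEIGHT))
        free(f"sheath_supply_{i}", "sheath_in", f"sb{i}", q_sheath,
             h=CIL_HEIGHT)
        edges.append(DesignEdge(f"sheath_bridge_{i}", f"sb{i}", f"obs{i}",
                                q_sheath, L_um=BRIDGE_LENGTH, w_um=BRIDGE_WIDTH,
                                h_um=CIL_HEIGHT))

    # observation channels to the shared outlet
    q_obs = q_feed + q_cell + q_sheath
    for i in range(N_CHANNELS):
        edges.append(DesignEdge(f"obs_channel_{i}", f"obs{i}", "out", q_obs,
                                L_um=OBS_LENGTH, w_um=OBS_WIDTH, h_um=OBS_HEIGHT))

    boundaries = {
        "chem_in": p_dilution_mbar,
        "buf_in": p_dilution_mbar,
        "cell_in": p_cell_mbar,
        "sheath_in": p_cell_mbar,
        "out": 0.0,
    }
    inlet_conc = {"chem_in": 1.0}
    return DesignConstraints(edges, boundaries, inlet_conc)


def design_mcd(p_dilution_mbar: float = 100.0,
               p_cell_mbar: float = 50.0) -> NetworkSpec:
    """Design the reference MCD network from its design constraints."""
    return design_network(mcd_constraints(p_dilution_mbar, p_cell_mbar))


def observation_feed_edges() -> list[str]:
    """Edge ids of the chemostimulus streams entering each observation channel."""
    return [f"feed_{i}" for i in range(N_CHANNELS)]


def mcd_dilution_profile(flow: FlowSolution) -> DilutionProfile:
    """Ci/C0 of the chemostimulus stream feeding each observation channel."""
    if not flow.edge_conc:
        propagate_concentration(flow)
    return DilutionProfile([flow.edge_conc[e] for e in observation_feed_edges()])


def solve_mcd(p_dilution_mbar: float = 100.0,
              p_cell_mbar: float = 50.0) -> FlowSolution:
    """Design, forward-solve and concentration-propagate the MCD in one call."""
    flow = solve_flow(design_mcd(p_dilution_mbar, p_cell_mbar))
    propagate_concentration(flow)
    return flow
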