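# Methods

This note documents the models implemented in `mcdkit`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic data
can and cannot tell you about real assays.

## Hydraulic circuit model

**Forward problem.** A microchannel network is treated as a resistor
network: each channel contributes a hydraulic resistance R (Δp = Q·R for
laminar, incompressible, fully developed flow), and mass conservation at
junctions closes the linear system. Node pressures solve the
conductance-weighted graph Laplacian with Dirichlet boundary pressures;
edge flows follow as Q = Δp/R. Rectangular ducts use the exact series
solution, evaluated with w ≥ h (the expression is symmetric under swapping
the two cross-section dimensions) and truncated at odd n ≤ 1001, which
leaves a relative truncation error below 2·10⁻¹³ even for square ducts at
negligible cost. All internal computation uses the self-consistent
(μm, mPa·s, mPa, μm³ s⁻¹) unit system in which the conventional resistance
unit mPa·s·μm⁻³ is native; interfaces speak mbar (1 mbar = 100 Pa) and
μl·min⁻¹.

Entrance effects, channel compliance, transients and non-Newtonian
rheology are out of scope; water viscosity (1.0 mPa·s at 20 °C) is the
default working fluid for all streams.

**Inverse design.** `design_network` receives boundary pressures, the
resistances of pre-characterised parts (micromixers, observation channels,
inter-layer bridges) and a complete, mass-consistent assignment of target
flows, and must choose the remaining resistances. Fixed-resistance edges
pin pressure *differences*, so nodes connected by them form rigid clusters
with known internal offsets; clusters containing a boundary node are fully
determined. The free clusters are placed by traversing the flow-directed
cluster graph in topological order and linearly interpolating pressure
along each cluster's *most constraining* downstream path — the route to a
determined pressure that admits the smallest uniform per-free-edge drop
after subtracting the fixed drops on the route. Taking the smallest
feasible drop guarantees that no downstream branch is left with a negative
pressure budget; simpler rules (nearest-neighbour interpolation, or
unconstrained least-squares equalisation of drops) were tried first and
both produce negative drops on the serial-dilution cascade, because the
buffer manifold connects a high-pressure inlet directly to every mixer
junction. The procedure is deterministic, and any remaining non-positive
drop raises an infeasibility error rather than being silently clipped.
Each designed resistance is finally realised as a channel length at a
configured cross-section (100 μm × 90 μm for dilution-layer resistors,
the 71-μm injection-layer height for cell channels).

**Reference device.** The packaged six-channel device is *regenerated*
from its design constraints rather than transcribed from fabricated
geometry: 100 mbar at the two dilution-layer inlets, 50 mbar at the two
cell-injection inlets, atmospheric outlet, micromixers fixed at
R_M = 0.0043 mPa·s·μm⁻³, and per-channel streams of 20/5/20 μl·min⁻¹
(chemostimulus/cells/buffer, the 4:1:4 stratification). The run-pressure
condition (200/140 mbar) is an accepted alternative configuration and
yields the same flow ratios by linearity. Mixer throughputs follow from
exact mass balance of the 1:9 dilution merges: walking up from the last
stage (which only exports its 20 μl·min⁻¹ stream) gives 20, 22, 22.2 and
22.22 μl·min⁻¹ — a nominal design point of ≈22 μl·min⁻¹ cannot hold at
all four mixers simultaneously once each stage also feeds its observation
channel, so the mass-consistent chain is used. Solute propagation assumes
complete mixing at junction outlets (the micromixers' job), making each
node's outgoing concentration the flow-weighted mean of its inflows; the
resulting chain is Cᵢ/C₀ = 10⁻ⁱ to floating-point accuracy.

## Stop-flow gradient

The cross-channel gradient is modelled in one dimension (the width
coordinate y ∈ [0, W], buffer wall at y = 0, chemostimulus band at high y;
depth and streamwise variation are neglected, matching how cross-channel
intensity profiles are measured). The stratified initial condition is a
step at 5W/9 — the thin central cell band is treated as zero-concentration
buffer — and evolves under ∂C/∂t = D ∂²C/∂y² with no-flux walls via the
cosine eigenfunction expansion, exact in time at any requested instant.

* **Diffusivity.** No single value is authoritative for "the
  chemostimulant": the default D = 5×10⁻¹⁰ m² s⁻¹ sits between fluorescein
  (≈4.25×10⁻¹⁰, the dye used to visualise gradients, chosen in such
  experiments precisely because it diffuses like serine) and small amino
  acids (≈8×10⁻¹⁰). Everything accepts an explicit D.
* **Truncation.** 512 modes; at the default D every mode above n ≈ 50 has
  decayed below 10⁻⁵ within one second, so Gibbs ringing from the step is
  irrelevant on assay timescales. At t = 0 exactly, the step itself is
  returned instead of its truncated series.
* **Grids.** Cell-centred y grids are used throughout: the discrete mean of
  every cosine mode vanishes identically on such a grid, so the spatial
  mean equals a₀ and mass is conserved to machine precision rather than to
  quadrature accuracy.
* **Validation.** The spectral solution is checked against an independent
  explicit finite-difference oracle (no-flux FTCS at CFL 0.4, grid aligned
  with the step edge) to < 10⁻⁴ max-abs, against the erfc similarity
  solution at early times, and against the mode-decay law. With
  D ∈ [4, 9]×10⁻¹⁰ m² s⁻¹ the cross-channel concentration difference decays
  by more than 80 % between 8 and 25 min, consistent with the practical
  ~10-min lifetime of one assay's gradient.

Chemoattractant consumption by dense cell populations (which can reverse
the late-time gradient in real assays) is deliberately not modelled; no
uptake kinetics are available to calibrate it.

## Synthetic swimmers

The generator produces position tables with the statistical structure the
analysis assumes; it is a stand-in for microscopy, not a fit to any
organism. Defaults describe a fast marine-bacterium-like population:
swim speed v = 45 μm s⁻¹, mean run duration τ = 0.45 s, non-motile
fraction 0.2 (source of the persistent central band in kymographs),
passive diffusivity 0.2 μm² s⁻¹ for the non-swimmers, and a cell count of
150 per channel, which with 75 imaging cycles gives 11 250 positions per
assay — inside the 7 000–16 000 range typical of the real recordings.

Dynamics: cells start uniformly in the central band (width W/9); motile
cells run straight and terminate runs with hazard 1/τ_eff, where

    τ_eff = τ · (1 + sign · χ · s(Cᵢ) · clip(d⁺, 0, 1)),

d⁺ is the along-path concentration derivative dC/dt normalised by Cᵢ/τ,
χ ≥ 0 the sensitivity, sign = ±1 for attractant/repellent, and
s(Cᵢ) = Cᵢ/(Cᵢ+K) an optional receptor-saturation factor (disabled by
default; the default per-channel normalisation makes the response
concentration-independent by construction, so panel experiments that
should show concentration ordering enable K). Run terminations reset the
direction by pattern: run–reverse–flick alternates 180° reversals with
±90° flicks whose handedness alternates deterministically (avoiding drift
from RNG ordering); run–tumble draws a uniform new angle. The simulation
is 2-D in (x, y) with a periodic 1-mm x-window; only y is analysed. Run
segments are subdivided at 0.05 s for gradient sampling, with the imaging
times spliced into the time grid so recordings are exact. Walls reflect;
reflection preserves the cell count. Identical seeds give bit-identical
tables, and a panel derives its six per-channel seeds deterministically
from one master seed.

What the generator does *not* emulate: hydrodynamic wall interactions,
cell–cell interactions, rotational diffusion, speed changes during
chemotaxis, consumption feedback on the gradient, and detection/tracking
noise of real microscopy. Passing pipeline tests therefore demonstrate
the correctness and statistical calibration of the *analysis*, not the
fidelity of any biological model.

## Chemotaxis metrics

* **Kymograph.** Default 25-μm bins (40 across the 1-mm channel; binning
  is an analysis choice, not a measured constant). Frames with zero cells
  are flagged missing, never zero-filled. A 250-μm central display band
  can be masked for visualisation (non-motile cells live there); the mask
  never touches the stored densities, and β is computed from the raw
  table, so the exclusion provably has no effect on it.
* **Accumulation index.** Regions are 200 μm wide and placed flush against
  the walls ([0, 200] and [W−200, W]); both width and placement are
  configurable. The denominator is fixed at the final frame.
* **Response summary.** β(t) is smoothed with a centred moving average
  (default 5 frames = 40 s at the 8-s cadence) whose window shrinks
  *symmetrically* near the ends — this keeps the smoother centred and
  unbiased for locally linear β(t) at the boundary frames, where a
  min-periods-style shrinking window would bias the pre-peak derivative.
  βmax is the signed extremum of the smoothed |β|, with ties broken toward
  the latest frame so a plateau peaks at its end and the pre-peak rate is
  well defined; the maximal rate is the extreme central-difference dβ/dt
  in the response direction over frames strictly before the peak.
* **Sørensen similarity.** The quantitative (abundance-based) variant on
  per-frame-normalised histogram masses, averaged over frames present in
  both kymographs; the binary presence/absence variant is rejected because
  kymographs are densities. It equals 1 − Bray–Curtis dissimilarity.

**Estimating βmax across replicates.** βmax is an extreme statistic: on
null data (χ = 0) its per-assay sampling noise at 150 cells is of order
0.2, comparable to weak true responses. Replicate assays are therefore
summarised by averaging their β(t) curves first and taking βmax of the
mean curve — the same order of operations used when replicate assay curves
are reported with shaded errors — rather than averaging per-replicate
maxima, which inflates weak responses by the noise floor. The sensitivity-
recovery test (5 χ levels × 10 seeds) uses this estimator and recovers a
strictly increasing response.

## Mixing metrics

The degree of mixing is computed as the standard deviation (RMS) of the
normalised intensity histogram. The defining formula is sometimes typeset
as a bare variance, but the stated endpoints (0.5 for a fully segregated
0/1 field) are only consistent with the RMS reading, which is used here;
as a variance the segregated endpoint would be 0.25. DOM is a histogram
statistic — invariant to pixel permutation — and is bounded by 0.5 for any
field with values in [0, 1]. Normalisation uses masked spatial means of
the low/high calibration images and is invariant to affine intensity
transforms applied to all three images. The 20-μm wall margin is applied
only when wall coordinates are declared (synthetic wall-free fields skip
it). Dilution reconstitution multiplies per-stage mean-intensity ratios;
ratios are only ever formed within an exposure-matched pair, so camera
gain and exposure cancel per stage. Flat-fielding, background subtraction
and camera noise modelling are out of scope.

## Pipeline

`run_panel` composes design → dilution → gradients → simulation → metrics
into one run driven by a single config (YAML-loadable) and master seed,
writing a manifest with a SHA-256 checksum for every output; identical
config + seed reproduce the bundle byte-for-byte. Stage failures abort
with a stage-tagged error and leave partial outputs plus a manifest marked
incomplete. Control panels (buffer in the chemical inlet ⇒ Cᵢ = 0
everywhere) and fixed-gradient panels (stock in both dilution inlets ⇒
Cᵢ = C₀ everywhere) are plain configuration choices.

## Problem sizes

Defaults were chosen so a full property run (flow-solver cross-checks,
gradient oracle at 999 grid points, 20-seed null calibration, 50-assay
sensitivity ladder at 150 cells × 75 frames) completes in a few minutes on
one core; all sizes (cells, grid points, modes, seeds) are parameters.

## Known limitations

* The fabricated device's channel-by-channel geometry is not reproduced;
  only the constraint-level design is, so designed lengths are one valid
  realisation, not the shipped layout.
* The gradient model is 1-D and consumption-free; late-time gradient
  reversal seen with dense, actively consuming populations will not occur.
* The swimmer model's weak-signal regime (d⁺ ~ 0.05 for these geometries)
  produces modest drifts; quantitative β magnitudes are not comparable to
  any particular organism.
* Position tables are analysed per frame; no track linking, and no
  swim-speed or turn-statistics estimation (the 8-s cadence is too coarse
  for those anyway).
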