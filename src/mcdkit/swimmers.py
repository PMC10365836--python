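"""Synthetic swimming-cell position data for the multiplexed assay.

The real device records bacterial positions by cycling a microscope over six
observation channels; this module generates position tables with the same
statistical structure so the analysis chain can be exercised and calibrated
without living cells.  The swimmer dynamics are a deliberately simple,
explicitly synthetic stand-in — a biased random walk, not a fit to any
strain:

* motile cells run at constant speed ``v`` and terminate runs with hazard
  1/τ_eff; on termination the direction resets according to the motility
  pattern (run--reverse--flick as in monotrichous marine bacteria, or
  run--tumble as in *E. coli*);
* chemotaxis enters through run-length modulation: while a cell experiences
  a rising concentration along its path, the mean run duration is extended
  (attractant) or shortened (repellent),

      τ_eff = τ · (1 + sign · χ · s(Ci) · clip(d⁺, 0, 1)),

  where d⁺ is the along-path dC/dt normalised by C_ref/τ (C_ref = Ci per
  channel by default), χ ≥ 0 is the chemotactic sensitivity and s(Ci) an
  optional receptor-saturation factor Ci/(Ci+K) enabled by setting the
  half-saturation constant K;
* a non-motile subpopulation stays in the central injection band, jittered
  by passive Brownian motion (emulating the persistent central band of
  non-swimmers seen in the assays);
* walls at y = 0, W reflect; x is periodic over a 1 mm imaging window.

Identical seeds produce bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .gradient import (
    ConcentrationField,
    StratificationSpec,
    concentration_at,
    solve_stratified,
)
from .hydraulics import DilutionProfile

__all__ = [
    "MotilityModel",
    "POSITION_COLUMNS",
    "imaging_schedule",
    "simulate_assay",
    "simulate_panel",
]

POSITION_COLUMNS = ["channel", "frame", "time_s", "x_um", "y_um", "cell_id"]

#: imaging window along the channel axis, μm (periodic)
X_WINDOW = 1000.0

#: run-segment subdivision for gradient sampling, s
DT_SAMPLE = 0.05


@dataclass(frozen=True)
class MotilityModel:
    """Parameters of the synthetic swimmer population."""

    pattern: str = "run-reverse-flick"   # or "run-tumble"
    v_um_s: float = 45.0                 # swim speed
    tau_s: float = 0.45                  # mean run duration
    chi: float = 0.0                     # chemotactic sensitivity, ≥ 0
    sign: int = 1                        # +1 attractant, −1 repellent
    f_nonmotile: float = 0.2             # non-motile fraction
    D_cell_um2_s: float = 0.2            # passive diffusivity of non-swimmers
    half_sat_conc: float | None = None   # K of s(Ci)=Ci/(Ci+K); None → s=1
    seed: int = 0

    def __post_init__(self):
        if self.pattern not in ("run-reverse-flick", "run-tumble"):
            raise ConfigurationError(f"unknown motility pattern {self.pattern!r}")
        if self.v_um_s <= 0 or self.tau_s <= 0:
            raise ConfigurationError("v and tau must be positive")
        if not 0.0 <= self.f_nonmotile <= 1.0:
            raise ConfigurationError("f_nonmotile must lie in [0, 1]")
        if self.chi < 0:
            raise ConfigurationError("chi must be ≥ 0")
        if self.sign not in (-1, 1):
            raise ConfigurationError("sign must be ±1")


def imaging_schedule(n_channels: int, n_cycles: int,
                     total_time_s: float) -> np.ndarray:
    """Staggered round-robin sampling times, shape (n_channels, n_cycles).

    The stage visits the channels cyclically ``n_cycles`` times in
    ``total_time_s``, so every channel is sampled with period
    ``total_time_s / n_cycles`` and channel k is offset by k/n_channels of a
    period (six channels over 10 min at 75 cycles give the 8-s effective
    imaging period of the real device).
    """
    if n_channels <= 0 or n_cycles <= 0 or total_time_s <= 0:
        raise ConfigurationError("schedule arguments must be positive")
    period = total_time_s / n_cycles
    offsets = np.arange(n_channels) * (period / n_channels)
    return offsets[:, None] + period * np.arange(n_cycles)[None, :]


def _reflect(y: np.ndarray, w: float) -> np.ndarray:
    y = np.mod(y, 2.0 * w)
    return np.where(y > w, 2.0 * w - y, y)


def simulate_assay(model: MotilityModel, field: ConcentrationField,
                   n_cells: int, schedule, channel: int = 0) -> pd.DataFrame:
    """Simulate one observation channel and sample it at the schedule times.

    ``field`` supplies C(y, t) for the channel (its time range must cover the
    schedule); ``schedule`` is the 1-D array of sampling times for this
    channel.  Returns a PositionTable data frame with columns
    ``channel, frame, time_s, x_um, y_um, cell_id`` and exactly
    ``n_cells × len(schedule)`` rows.
    """
    schedule = np.sort(np.asarray(schedule, dtype=float))
    if schedule.size == 0:
        return pd.DataFrame(columns=POSITION_COLUMNS)
    if schedule[-1] > field.t_s[-1] + 1e-9 or schedule[0] < field.t_s[0] - 1e-9:
        raise ConfigurationError("field does not cover the imaging schedule")

    w = field.W_um
    ci = field.source_conc
    rng = np.random.default_rng(model.seed)

    spec = StratificationSpec(W_um=w, source_conc=ci)
    lo, hi = spec.cell_band
    y = rng.uniform(lo, hi, n_cells)
    x = rng.uniform(0.0, X_WINDOW, n_cells)
    motile = rng.random(n_cells) >= model.f_nonmotile
    theta = rng.uniform(0.0, 2.0 * np.pi, n_cells)
    # run-reverse-flick bookkeeping: next turn type and flick handedness
    next_reverse = np.ones(n_cells, dtype=bool)
    flick_sign = np.ones(n_cells)

    c_ref = ci if ci > 0 else None
    sat = 1.0
    if model.half_sat_conc is not None:
        sat = ci / (ci + model.half_sat_conc) if ci > 0 else 0.0

    # time grid: fixed sampling step, with schedule times spliced in exactly
    t0 = field.t_s[0]
    grid = np.union1d(np.arange(t0, schedule[-1], DT_SAMPLE), schedule)
    record_at = np.isin(grid, schedule)

    c_prev = np.asarray(concentration_at(field, y, np.full(n_cells, grid[0])))
    frames = {}
    frame_of = {t: i for i, t in enumerate(schedule)}
    if record_at[0]:
        frames[grid[0]] = (x.copy(), y.copy())

    sqrt2d = np.sqrt(2.0 * model.D_cell_um2_s)
    for i in range(1, grid.size):
        dt = grid[i] - grid[i - 1]
        if dt <= 0:
            continue
        # motile advance
        x = np.where(motile, x + model.v_um_s * dt * np.cos(theta), x)
        y_new = np.where(motile, y + model.v_um_s * dt * np.sin(theta), y)
        # non-motile Brownian jitter (drawn for all cells to keep the RNG
        # stream independent of the motility split)
        step = rng.normal(0.0, sqrt2d * np.sqrt(dt), (2, n_cells))
        x = np.where(motile, x, x + step[0])
        y_new = np.where(motile, y_new, y_new + step[1])

        y = _reflect(y_new, w)
        x = np.mod(x, X_WINDOW)

        c_now = np.asarray(concentration_at(field, y, np.full(n_cells, grid[i])))
        if c_ref is not None and model.chi > 0.0:
            d_plus = np.clip((c_now - c_prev) / dt * (model.tau_s / c_ref),
                             0.0, 1.0)
            tau_eff = model.tau_s * np.maximum(
                1.0 + model.sign * model.chi * sat * d_plus, 0.05)
        else:
            tau_eff = np.full(n_cells, model.tau_s)
        c_prev = c_now

        # run termination with hazard 1/τ_eff
        ends = motile & (rng.random(n_cells) < -np.expm1(-dt / tau_eff))
        if model.pattern == "run-tumble":
            new_theta = rng.uniform(0.0, 2.0 * np.pi, n_cells)
            theta = np.where(ends, new_theta, theta)
        else:
            turn = np.where(next_reverse, np.pi, flick_sign * np.pi / 2.0)
            theta = np.where(ends, theta + turn, theta)
            # flick handedness alternates deterministically after each flick
            flick_sign = np.where(ends & ~next_reverse, -flick_sign, flick_sign)
            next_reverse = np.where(ends, ~next_reverse, next_reverse)

        if record_at[i]:
            frames[grid[i]] = (x.copy(), y.copy())

    rows = []
    ids = np.arange(n_cells)
    for t in schedule:
        fx, fy = frames[t]
        rows.append(pd.DataFrame({
            "channel": channel, "frame": frame_of[t], "time_s": t,
            "x_um": fx, "y_um": fy, "cell_id": ids,
        }))
    return pd.concat(rows, ignore_index=True)[POSITION_COLUMNS]


def simulate_panel(model: MotilityModel, dilution: DilutionProfile,
                   spec: StratificationSpec | None = None,
                   n_cells: int = 150, n_cycles: int = 75,
                   total_time_s: float = 600.0,
                   D_m2_s: float | None = None,
                   master_seed: int = 0, ny: int = 256,
                   field_dt_s: float = 2.0) -> pd.DataFrame:
    """Simulate one full multiplexed run: six channels, one master seed.

    Each channel i gets a gradient built from the dilution profile's Ci
    (the control channel, C = 0, is simulated identically) and its own
    deterministic sub-seed derived from ``master_seed``.  Returns the
    concatenated PositionTable for all channels.
    """
    if len(dilution) != 6:
        raise ConfigurationError("dilution profile must have 6 channels")
    if spec is None:
        spec = StratificationSpec()
    from .gradient import DEFAULT_DIFFUSIVITY
    if D_m2_s is None:
        D_m2_s = DEFAULT_DIFFUSIVITY

    sched = imaging_schedule(len(dilution), n_cycles, total_time_s)
    seeds = np.random.SeedSequence(master_seed).generate_state(len(dilution))
    times = np.union1d(np.arange(0.0, total_time_s + field_dt_s, field_dt_s),
                       [sched.max()])

    tables = []
    for ch, ci in enumerate(dilution):
        ch_spec = replace(spec, source_conc=float(ci))
        fld = solve_stratified(ch_spec, times, ny=ny, D_m2_s=D_m2_s)
        ch_model = replace(model, seed=int(seeds[ch] % 2 ** 31))
        tables.append(simulate_assay(ch_model, fld, n_cells, sched[ch],
                                     channel=ch))
    return pd.concat(tables, ignore_index=True)
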