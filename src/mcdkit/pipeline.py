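"""End-to-end synthetic multiplexed assay: design → dilution → gradients →
swimmer simulation → chemotaxis metrics → report bundle.

:func:`run_panel` composes the whole workflow for one device run and writes
a reproducible bundle: the designed network, the dilution table, per-channel
gradient fields, the position table, kymographs, β(t) series, a per-channel
response summary, and a manifest with a checksum for every output.  The
same configuration and seed always produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, device
from .accumulation import (
    DEFAULT_BIN_WIDTH,
    DEFAULT_REGION_WIDTH,
    DEFAULT_SMOOTH_WINDOW,
    accumulation_index,
    kymograph,
    response_summary,
)
from .errors import ConfigurationError
from .gradient import DEFAULT_DIFFUSIVITY, StratificationSpec, solve_stratified
from .hydraulics import DilutionProfile, propagate_concentration, solve_flow
from .swimmers import MotilityModel, simulate_panel

__all__ = ["PipelineConfig", "run_panel"]

log = logging.getLogger("mcdkit.pipeline")


@dataclass
class PipelineConfig:
    """Configuration of one synthetic multiplexed run."""

    # hydraulic design
    p_dilution_mbar: float = 100.0
    p_cell_mbar: float = 50.0
    chem_inlet_conc: float = 1.0      # C0 fraction at the chemical inlet
    buffer_inlet_conc: float = 0.0    # raised to C0 for fixed-gradient runs
    # gradient
    W_um: float = 1000.0
    fractions: tuple[float, float, float] = (4 / 9, 1 / 9, 4 / 9)
    D_m2_s: float = DEFAULT_DIFFUSIVITY
    ny: int = 256
    # swimmers
    motility: MotilityModel = field(default_factory=MotilityModel)
    n_cells: int = 150
    n_channels: int = 6
    n_cycles: int = 75
    total_time_s: float = 600.0
    # analysis
    bin_width_um: float = DEFAULT_BIN_WIDTH
    region_width_um: float = DEFAULT_REGION_WIDTH
    smoothing_window: int = DEFAULT_SMOOTH_WINDOW
    # reproducibility
    master_seed: int = 0

    def __post_init__(self):
        if self.n_channels != device.N_CHANNELS:
            raise ConfigurationError(
                f"the multiplexed device has {device.N_CHANNELS} channels")
        if isinstance(self.motility, dict):
            self.motility = MotilityModel(**self.motility)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if "fractions" in doc:
            doc["fractions"] = tuple(doc["fractions"])
        return cls(**doc)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fractions"] = list(self.fractions)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_field_tsv(path: Path, fld, header: dict) -> None:
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        fh.write("time_s\t" + "\t".join(f"{y:.6g}" for y in fld.y_um) + "\n")
        for t, row in zip(fld.t_s, fld.values):
            fh.write(f"{t:.6g}\t" + "\t".join(f"{v:.8g}" for v in row) + "\n")


def run_panel(config: PipelineConfig, out_dir, seed: int | None = None) -> dict:
    """Run the full synthetic panel and write the report bundle to ``out_dir``.

    Returns the summary dictionary (per-channel Ci, βmax, t(βmax) and max
    dβ/dt).  ``seed`` overrides ``config.master_seed`` when given.
    """
    t_start = time.perf_counter()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.master_seed if seed is None else int(seed)
    manifest = {"mcdkit_version": __version__, "seed": seed,
                "config": config.to_dict(), "outputs": {}, "complete": False}
    written: list[Path] = []

    def emit(path: Path):
        manifest["outputs"][path.name] = _sha256(path)
        written.append(path)

    def save_manifest():
        manifest["config_hash"] = hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    stage = "design"
    try:
        log.info("stage %s", stage)
        spec = device.design_mcd(config.p_dilution_mbar, config.p_cell_mbar)
        spec.inlet_conc = {"chem_in": config.chem_inlet_conc,
                           "buf_in": config.buffer_inlet_conc}
        (out / "network.json").write_text(spec.to_json())
        emit(out / "network.json")

        stage = "dilution"
        log.info("stage %s", stage)
        flow = solve_flow(spec)
        propagate_concentration(flow)
        feed = device.observation_feed_edges()
        fractions = [flow.edge_conc[e] for e in feed]
        dil = DilutionProfile(fractions)
        pd.DataFrame({"channel": range(len(feed)),
                      "Ci_over_C0": fractions}).to_csv(
            out / "dilution.csv", index=False)
        emit(out / "dilution.csv")

        stage = "gradient"
        log.info("stage %s", stage)
        times = np.arange(0.0, config.total_time_s + 2.0, 2.0)
        strat = StratificationSpec(config.W_um, config.fractions)
        for ch, ci in enumerate(fractions):
            fld = solve_stratified(
                StratificationSpec(config.W_um, config.fractions, float(ci)),
                times, ny=config.ny, D_m2_s=config.D_m2_s)
            p = out / f"gradient_ch{ch}.tsv"
            _write_field_tsv(p, fld, {
                "W_um": config.W_um, "D_m2_s": config.D_m2_s,
                "Ci_over_C0": float(ci), "fractions": list(config.fractions)})
            emit(p)

        stage = "simulate"
        log.info("stage %s", stage)
        table = simulate_panel(config.motility, dil, strat,
                               n_cells=config.n_cells,
                               n_cycles=config.n_cycles,
                               total_time_s=config.total_time_s,
                               D_m2_s=config.D_m2_s, master_seed=seed,
                               ny=config.ny)
        table.to_csv(out / "positions.csv", index=False,
                     float_format="%.6g")
        emit(out / "positions.csv")

        stage = "metrics"
        log.info("stage %s", stage)
        summary_rows = []
        for ch in range(config.n_channels):
            sub = table[table["channel"] == ch]
            km = kymograph(sub, config.bin_width_um, config.W_um)
            np.savetxt(out / f"kymograph_ch{ch}.tsv", km.density,
                       delimiter="\t", fmt="%.8g")
            emit(out / f"kymograph_ch{ch}.tsv")
            acc = accumulation_index(sub, config.W_um, config.region_width_um)
            pd.DataFrame({"time_s": acc.times, "beta": acc.beta,
                          "Np": acc.n_pos, "Nn": acc.n_neg}).to_csv(
                out / f"beta_ch{ch}.csv", index=False, float_format="%.8g")
            emit(out / f"beta_ch{ch}.csv")
            rs = response_summary(acc, config.smoothing_window)
            summary_rows.append({
                "channel": ch, "Ci_over_C0": fractions[ch],
                "beta_max": rs.beta_max, "t_max_s": rs.t_max_s,
                "max_rate_per_s": rs.max_rate_per_s})
        summary = pd.DataFrame(summary_rows)
        summary.to_csv(out / "summary.csv", index=False, float_format="%.8g")
        emit(out / "summary.csv")
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        save_manifest()
        raise ConfigurationError(f"pipeline stage {stage!r} failed: {exc}") \
            from exc

    manifest["complete"] = True
    save_manifest()
    log.info("panel complete in %.1f s (%d files)",
             time.perf_counter() - t_start, len(written) + 1)
    return {"summary": summary_rows, "out_dir": str(out), "seed": seed}
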