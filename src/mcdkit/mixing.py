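"""Micromixer and serial-dilution image metrics.

The herringbone micromixers in the dilution layer are validated with
fluorescent-dye imaging: calibration images at a low and a high dye
concentration bracket the intensity scale, test images are normalised to
that scale, and mixing progress along the channel is scored by the degree
of mixing

    DOM = sqrt(⟨(I − ⟨I⟩)²⟩),

the spatial standard deviation of the normalised intensity.  A perfectly
segregated two-level field (half pixels 0, half 1) scores 0.5 and a uniform
field 0; the streams are considered mixed when DOM ≤ 0.05, i.e. 90 %
complete mixing from a segregated start.  (The RMS convention is fixed by
those published endpoints; read as a plain variance the same formula would
score a segregated field 0.25.)

Pixels within 20 μm of a channel wall are conventionally excluded (optical
reflection/refraction artefacts); the mask is applied only when wall
positions are declared.

The serial-dilution chain is reconstituted from pairs of mean intensities
measured at consecutive stages with matched exposure:

    Ci/C0 = Π_{n=1..i} ⟨I_n⟩ / ⟨I_{n−1}⟩ ,

so each ratio is exposure-invariant even though absolute intensities are
not comparable across pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DegenerateCalibrationError, NoDataError

__all__ = [
    "IntensityField",
    "MixingResult",
    "WALL_MARGIN_UM",
    "normalize_intensity",
    "degree_of_mixing",
    "mixed_criterion",
    "reconstitute_dilution",
]

#: wall-exclusion margin, μm
WALL_MARGIN_UM = 20.0

MIXED_THRESHOLD = 0.05


@dataclass
class IntensityField:
    """A single-plane intensity image with an optional inclusion mask."""

    values: np.ndarray
    pixel_size_um: float = 1.0
    mask: np.ndarray | None = None   # True = included

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("intensity field must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensity field contains non-finite values")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape mismatch")

    @classmethod
    def from_text(cls, path, pixel_size_um: float = 1.0) -> "IntensityField":
        """Whitespace-delimited matrix text."""
        return cls(np.loadtxt(path), pixel_size_um)

    @classmethod
    def from_tiff(cls, path, pixel_size_um: float = 1.0) -> "IntensityField":
        import tifffile
        return cls(tifffile.imread(Path(path)), pixel_size_um)

    def with_wall_margin(self, wall_rows: tuple[float, float] | None = None,
                         margin_um: float = WALL_MARGIN_UM) -> "IntensityField":
        """Exclude pixels within ``margin_um`` of the declared channel walls.

        ``wall_rows`` gives the wall positions (μm) along the row axis; when
        None the walls are taken at the image edges.
        """
        n_rows = self.values.shape[0]
        if wall_rows is None:
            wall_rows = (0.0, n_rows * self.pixel_size_um)
        rows_um = (np.arange(n_rows) + 0.5) * self.pixel_size_um
        keep = (rows_um >= wall_rows[0] + margin_um) & \
               (rows_um <= wall_rows[1] - margin_um)
        mask = self.mask & keep[:, None]
        return IntensityField(self.values, self.pixel_size_um, mask)

    def masked_mean(self) -> float:
        if not self.mask.any():
            raise NoDataError("empty mask")
        return float(self.values[self.mask].mean())


@dataclass
class MixingResult:
    dom_per_cycle: list[float]
    mixed_at_cycle: int | None
    threshold: float = MIXED_THRESHOLD
    wall_margin_um: float | None = None
    extra: dict = field(default_factory=dict)


def normalize_intensity(raw: IntensityField, lo_ref: IntensityField,
                        hi_ref: IntensityField) -> IntensityField:
    """Scale a raw image to the calibration range: (I − ⟨I_lo⟩)/(⟨I_hi⟩ − ⟨I_lo⟩).

    ⟨·⟩ is the masked spatial mean of each calibration image.  Output values
    may slightly exceed [0, 1] through noise and are deliberately not
    clipped.
    """
    lo = lo_ref.masked_mean()
    hi = hi_ref.masked_mean()
    if hi <= lo:
        raise DegenerateCalibrationError(
            f"calibration means not separated (lo={lo}, hi={hi})")
    return IntensityField((raw.values - lo) / (hi - lo), raw.pixel_size_um,
                          raw.mask.copy())


def degree_of_mixing(normalized: IntensityField) -> float:
    """DOM of a normalised field: the spatial standard deviation of the
    unmasked pixels (0.5 = fully segregated 0/1 field, 0 = fully mixed)."""
    if not normalized.mask.any():
        raise NoDataError("empty mask")
    return float(np.std(normalized.values[normalized.mask]))


def mixed_criterion(dom_series, threshold: float = MIXED_THRESHOLD) -> int | None:
    """First cycle (1-based) at which DOM ≤ threshold, or None if never.

    The default threshold 0.05 is 10 % of the fully segregated DOM of 0.5,
    i.e. 90 % complete mixing.
    """
    series = list(dom_series)
    if not series:
        raise NoDataError("empty DOM series")
    for i, dom in enumerate(series):
        if dom <= threshold:
            return i + 1
    return None


def reconstitute_dilution(stage_mean_pairs) -> list[float]:
    """Dilution-chain concentrations from per-stage mean-intensity pairs.

    Each pair (⟨I_{n−1}⟩, ⟨I_n⟩) is acquired with matched exposure, so its
    ratio estimates the single-stage dilution factor; the cumulative product
    over stages reconstitutes [C1/C0, ..., Cn/C0].  An empty chain returns
    [] (C0/C0 = 1 needs no measurement).
    """
    ratios = []
    for prev, cur in stage_mean_pairs:
        if prev <= 0 or cur <= 0:
            raise ValueError("stage mean intensities must be positive")
        ratios.append(cur / prev)
    return list(np.cumprod(ratios)) if ratios else []
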