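"""Concentration conversion and summary statistics.

Two concentration conventions are supported:

* HEMOCYTOMETER — the manual-chamber convention: mean grid count × 10,000
  (volume and unit conversion factor for the standard 1 mm × 1 mm × 0.1 mm
  grid square) × dilution factor.
* AREA_VOLUME — the imaging convention: count / (FOV area [mm²] × chamber
  depth [mm]) × 1000 (mm³ → mL) × dilution factor.

Summary statistics follow the conventions of instrument-comparison studies:

* viability % — STANDARD mode (total − dead)/total × 100; AS_PRINTED mode
  (live − dead)/live × 100, which can be negative and is kept only for
  fidelity with reports that use that form.
* error rate ER = (Σx_i − Σx_j)/Σx_i × 100, x_i the reference instrument
  (hemocytometer), x_j the instrument under test.
* coefficient of variation CV = sample SD (n−1 denominator) / mean × 100
  over replicate measurements.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, UndefinedMetricError

__all__ = [
    "ConcentrationMode",
    "ConcentrationParams",
    "ViabilityCounts",
    "concentration",
    "viability_percent",
    "error_rate",
    "coefficient_of_variation",
    "mean_ratio",
    "fov_area",
    "linear_fit_r2",
    "FOV_LENSFREE_MM",
    "FOV_COMMERCIAL_MM",
    "FOV_HEMOCYTOMETER_MM",
    "HEMOCYTOMETER_VOLUME_FACTOR",
]

# FOV dimensions (width, height) in mm of the instruments compared throughout:
# the lens-free analyzer's full 5-Mpx sensor, a microscopy-based commercial
# counter, and the 1 mm × 1 mm hemocytometer grid square.
FOV_LENSFREE_MM = (5.70, 4.28)
FOV_COMMERCIAL_MM = (2.15, 1.62)
FOV_HEMOCYTOMETER_MM = (1.0, 1.0)

HEMOCYTOMETER_VOLUME_FACTOR = 10_000.0  # per-mL conversion for the 0.1 µL grid square


class ConcentrationMode(Enum):
    HEMOCYTOMETER = "hemocytometer"
    AREA_VOLUME = "area_volume"


@dataclass(frozen=True)
class ConcentrationParams:
    """Parameters of the count → cells/mL conversion.

    ``chamber_depth_mm`` is the sample layer thickness over the sensor; 0.1 mm
    is a typical counting-chamber depth and serves as an illustrative default,
    not a device constant.
    """

    mode: ConcentrationMode = ConcentrationMode.AREA_VOLUME
    volume_factor: float = HEMOCYTOMETER_VOLUME_FACTOR
    fov_area_mm2: float | None = None
    chamber_depth_mm: float = 0.1
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.volume_factor <= 0:
            raise ConfigurationError("volume_factor must be > 0")
        if self.fov_area_mm2 is not None and self.fov_area_mm2 <= 0:
            raise ConfigurationError("fov_area_mm2 must be > 0")
        if self.chamber_depth_mm <= 0:
            raise ConfigurationError("chamber_depth_mm must be > 0")
        if self.dilution_factor < 1:
            raise ConfigurationError("dilution_factor must be >= 1")


def concentration(count: float, params: ConcentrationParams) -> float:
    """Convert a cell count (or mean count) to cells/mL."""
    if count < 0:
        raise ValueError("count must be >= 0")
    if params.mode is ConcentrationMode.HEMOCYTOMETER:
        return count * params.volume_factor * params.dilution_factor
    if params.fov_area_mm2 is None:
        raise ConfigurationError("AREA_VOLUME mode requires fov_area_mm2")
    volume_mm3 = params.fov_area_mm2 * params.chamber_depth_mm
    return count / volume_mm3 * 1000.0 * params.dilution_factor


@dataclass(frozen=True)
class ViabilityCounts:
    n_total: int
    n_live: int
    n_dead: int

    def __post_init__(self) -> None:
        if self.n_live + self.n_dead != self.n_total:
            raise ValueError("n_live + n_dead must equal n_total")


def viability_percent(counts: ViabilityCounts, mode: str = "standard") -> float:
    """Viability in percent.

    ``standard``: (total − dead)/total × 100, always in [0, 100].
    ``as_printed``: (live − dead)/live × 100, ≤ 100 and possibly negative —
    a literal transcription of one reported form, retained for fidelity.
    """
    if mode == "standard":
        if counts.n_total == 0:
            raise UndefinedMetricError("viability undefined for zero cells")
        return (counts.n_total - counts.n_dead) / counts.n_total * 100.0
    if mode == "as_printed":
        if counts.n_live == 0:
            raise UndefinedMetricError("as-printed viability undefined for zero live cells")
        return (counts.n_live - counts.n_dead) / counts.n_live * 100.0
    raise ConfigurationError(f"unknown viability mode: {mode!r}")


def error_rate(reference: Sequence[float], test: Sequence[float]) -> float:
    """ER (%) of a paired series: (Σref − Σtest)/Σref × 100."""
    ref = np.asarray(reference, dtype=np.float64)
    tst = np.asarray(test, dtype=np.float64)
    if ref.shape != tst.shape or ref.size < 1:
        raise ConfigurationError("reference and test series must have equal length >= 1")
    total = ref.sum()
    if total == 0:
        raise UndefinedMetricError("ER undefined: reference sum is zero")
    return float((total - tst.sum()) / total * 100.0)


def coefficient_of_variation(values: Sequence[float]) -> float:
    """CV (%) of replicate observations: sample SD (n−1) over mean × 100."""
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2:
        raise UndefinedMetricError("CV requires at least 2 observations")
    mu = x.mean()
    if mu == 0:
        raise UndefinedMetricError("CV undefined: mean is zero")
    return float(x.std(ddof=1) / mu * 100.0)


def mean_ratio(numerators: Sequence[float], denominators: Sequence[float]) -> float:
    """Mean of elementwise ratios — the improvement factor between two
    instruments' per-category summary statistics."""
    num = np.asarray(numerators, dtype=np.float64)
    den = np.asarray(denominators, dtype=np.float64)
    if num.shape != den.shape or num.size < 1:
        raise ConfigurationError("series must have equal length >= 1")
    if np.any(den == 0):
        raise UndefinedMetricError("ratio undefined: zero denominator")
    return float((num / den).mean())


def fov_area(width_mm: float, height_mm: float) -> float:
    """Field-of-view area in mm²."""
    if width_mm <= 0 or height_mm <= 0:
        raise ConfigurationError("FOV dimensions must be > 0")
    return width_mm * height_mm


def linear_fit_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """R² of the least-squares line y = a·x + b."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ConfigurationError("need at least 3 paired points")
    a, b = np.polyfit(x, y, 1)
    resid = y - (a * x + b)
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        raise UndefinedMetricError("R² undefined: response has zero variance")
    return float(1.0 - (resid**2).sum() / ss_tot)
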