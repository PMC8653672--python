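"""Competitive 4-parameter-logistic calibration curves.

In a competitive chemiluminescent immunoassay the analyte in the sample
competes with an enzyme-labelled conjugate for antibody binding, so the
emitted light (RLU) falls monotonically with concentration:

    RLU(c) = bottom + (top - bottom) / (1 + (c / c50)**slope)

``top`` is the zero-concentration plateau, ``bottom`` the fully-competed
background, ``c50`` the half-displacement concentration and ``slope`` the
Hill coefficient. The curve is parameterised on the assay-level (diluted)
concentration scale; the screening stage multiplies back the sample
dilution factor when reporting concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Union

import numpy as np

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class CalibrationModel:
    """4PL curve parameters for one analyte (RLU vs µg/kg, decreasing)."""

    analyte: str
    top: float
    bottom: float
    c50: float
    slope: float

    def __post_init__(self) -> None:
        if not self.top > self.bottom >= 0:
            raise ValueError(f"{self.analyte}: require top > bottom >= 0")
        if self.c50 <= 0:
            raise ValueError(f"{self.analyte}: c50 must be positive")
        if self.slope <= 0:
            raise ValueError(f"{self.analyte}: slope must be positive")


class ConcStatus(str, Enum):
    OK = "ok"
    BELOW_DETECTION = "below_detection"  # signal at/above the zero plateau
    SATURATED = "saturated"              # signal at/below the background


@dataclass(frozen=True)
class ConcEstimate:
    """Back-calculated concentration with its censoring status.

    ``value`` is NaN for saturated signals (true concentration above the
    calibration range; a number would be fabricated) and 0.0 for signals at
    or above the zero-concentration plateau.
    """

    value: float
    status: ConcStatus

    @property
    def censored(self) -> bool:
        return self.status is ConcStatus.SATURATED


def signal_at(conc: ArrayLike, model: CalibrationModel) -> ArrayLike:
    """Expected RLU at a nonnegative assay-level concentration."""
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be nonnegative")
    rlu = model.bottom + (model.top - model.bottom) / (
        1.0 + (c / model.c50) ** model.slope
    )
    return float(rlu) if np.isscalar(conc) or c.ndim == 0 else rlu


def inverse_signal(rlu: float, model: CalibrationModel) -> ConcEstimate:
    """Closed-form inverse of :func:`signal_at` with boundary flags.

    Strictly interior signals (bottom < rlu < top) invert exactly; a signal
    at or above ``top`` is reported as 0 µg/kg (below detection), one at or
    below ``bottom`` as saturated (censored).
    """
    if rlu >= model.top:
        return ConcEstimate(0.0, ConcStatus.BELOW_DETECTION)
    if rlu <= model.bottom:
        return ConcEstimate(math.nan, ConcStatus.SATURATED)
    ratio = (model.top - model.bottom) / (rlu - model.bottom) - 1.0
    conc = model.c50 * ratio ** (1.0 / model.slope)
    return ConcEstimate(conc, ConcStatus.OK)


# Illustrative default curves for the packaged panel. Tops sit near the
# observed blank-signal magnitudes of the validation study and mid-curve
# signals near its spiked-cohort magnitudes; they are plausible kit-like
# curves, not fitted instrument calibrations.
DEFAULT_CALIBRATIONS: dict[str, CalibrationModel] = {
    "SDZ": CalibrationModel("SDZ", top=5050.0, bottom=152.0, c50=0.8693, slope=1.2),
    "SDIM": CalibrationModel("SDIM", top=3480.0, bottom=104.0, c50=2.984, slope=1.1),
    "SQX": CalibrationModel("SQX", top=7840.0, bottom=235.0, c50=1.005, slope=1.3),
    "SMTZ": CalibrationModel("SMTZ", top=3150.0, bottom=94.0, c50=1.483, slope=1.2),
    "SMXZ": CalibrationModel("SMXZ", top=3200.0, bottom=96.0, c50=0.5613, slope=1.15),
    "STZ": CalibrationModel("STZ", top=7340.0, bottom=220.0, c50=0.2655, slope=1.4),
    "SSX": CalibrationModel("SSX", top=3750.0, bottom=112.0, c50=0.955, slope=1.3),
    "SPD": CalibrationModel("SPD", top=2750.0, bottom=82.0, c50=1.692, slope=1.1),
    "SMZ": CalibrationModel("SMZ", top=6590.0, bottom=198.0, c50=0.8871, slope=1.35),
    "SMMX": CalibrationModel("SMMX", top=2010.0, bottom=60.0, c50=8.69, slope=1.0),
    "SMPD": CalibrationModel("SMPD", top=3590.0, bottom=108.0, c50=1.644, slope=1.2),
    "SCPD": CalibrationModel("SCPD", top=7870.0, bottom=236.0, c50=1.649, slope=1.1),
    "DAP": CalibrationModel("DAP", top=4950.0, bottom=148.0, c50=2.18, slope=1.2),
    "SDX": CalibrationModel("SDX", top=2850.0, bottom=86.0, c50=2.066, slope=1.25),
    "TMPM": CalibrationModel("TMPM", top=1520.0, bottom=46.0, c50=1.05, slope=1.15),
}


def default_models() -> dict[str, CalibrationModel]:
    """Copy of the packaged default calibration curves, keyed by analyte."""
    return dict(DEFAULT_CALIBRATIONS)
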