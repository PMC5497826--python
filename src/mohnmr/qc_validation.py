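"""Series QC (control recovery gate) and validation statistics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .model import Spectrum1D
from .pulcon_quant import (
    EreticFactor,
    IntegrationRegion,
    default_region_scheme,
    quantify,
)

__all__ = [
    "ControlCheck",
    "ControlGateError",
    "ValidationSeries",
    "control_recovery",
    "coefficient_of_variation",
    "spike_recovery",
    "RECOVERY_GATE",
]

#: inclusive recovery gate for the series control, percent
RECOVERY_GATE = (95.0, 105.0)

#: nominal control concentration, mg/L
CONTROL_NOMINAL_MG_L = 2500.0


class ControlGateError(RuntimeError):
    """Raised when quantification is requested for a series whose control
    recovery fell outside the gate."""


@dataclass(frozen=True)
class ControlCheck:
    """Outcome of the end-of-series control-solution check."""

    nominal_conc: float  # mg/L
    measured_conc: float  # mg/L
    recovery: float  # percent
    passed: bool

    @staticmethod
    def from_measurement(measured_mg_l: float,
                         nominal_mg_l: float = CONTROL_NOMINAL_MG_L) -> "ControlCheck":
        recovery = measured_mg_l / nominal_mg_l * 100.0
        passed = RECOVERY_GATE[0] <= recovery <= RECOVERY_GATE[1]
        return ControlCheck(nominal_mg_l, measured_mg_l, recovery, passed)

    def require_passed(self) -> None:
        if not self.passed:
            raise ControlGateError(
                f"control recovery {self.recovery:.1f}% outside "
                f"{RECOVERY_GATE[0]:.0f}–{RECOVERY_GATE[1]:.0f}% gate; "
                "series results are invalid"
            )


def control_recovery(
    spec: Spectrum1D,
    eretic: EreticFactor,
    scheme: Optional[Dict[str, IntegrationRegion]] = None,
    nominal_mg_l: float = CONTROL_NOMINAL_MG_L,
) -> ControlCheck:
    """Quantify the cyclohexane control singlet and gate the series.

    The gate is the closed interval [95 %, 105 %]: boundary recoveries pass.
    """
    scheme = scheme or default_region_scheme()
    region = scheme["control_cyclohexane"]
    res = quantify(spec, region, eretic)
    measured_mg_l = res.concentration * 1000.0
    return ControlCheck.from_measurement(measured_mg_l, nominal_mg_l)


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample standard deviation over mean, in percent."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV needs at least two values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(arr.std(ddof=1) / mean * 100.0)


@dataclass
class ValidationSeries:
    """Spiked-vs-measured validation data for one analyte."""

    analyte: str
    spiked: List[float]  # g/100 g
    measured: List[float]  # g/100 g

    def __post_init__(self) -> None:
        if len(self.spiked) != len(self.measured):
            raise ValueError("spiked and measured lengths differ")
        if any(s <= 0 for s in self.spiked):
            raise ValueError("spiked levels must be positive")

    @property
    def recoveries(self) -> List[float]:
        return [m / s * 100.0 for s, m in zip(self.spiked, self.measured)]

    @property
    def mean_recovery(self) -> float:
        return float(np.mean(self.recoveries))

    @property
    def cv(self) -> float:
        return coefficient_of_variation(self.recoveries)


def spike_recovery(series: ValidationSeries) -> Dict[str, object]:
    """Per-level recovery percentages plus mean and CV summary."""
    recs = series.recoveries
    return {
        "analyte": series.analyte,
        "recoveries": recs,
        "mean_recovery": float(np.mean(recs)),
        "cv": coefficient_of_variation(recs) if len(recs) >= 2 else 0.0,
    }
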