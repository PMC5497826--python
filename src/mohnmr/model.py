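"""Core data model shared by every pipeline stage.

The central object is :class:`Spectrum1D`, a frequency-domain real spectrum
on a descending ppm axis carrying the acquisition and sample-preparation
metadata that PULCON quantification needs.  :class:`FidRecord` holds raw
time-domain data prior to Fourier transformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["SamplePrep", "FidRecord", "Spectrum1D"]

#: relative tolerance for "constant grid spacing" on the ppm axis
_GRID_RTOL = 1e-9


@dataclass(frozen=True)
class SamplePrep:
    """Sample preparation metadata: mass dissolved and solution volume.

    Parameters
    ----------
    sample_mass : float
        Mass of sample weighed into the solution, in mg.
    solution_volume : float
        Volume of the solution, in mL.
    tube_volume_used : float, optional
        Volume actually transferred to the NMR tube, in mL (informational;
        it does not enter the mass-fraction arithmetic).
    """

    sample_mass: float
    solution_volume: float
    tube_volume_used: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.sample_mass > 0:
            raise ValueError(f"sample_mass must be > 0 mg, got {self.sample_mass}")
        if not self.solution_volume > 0:
            raise ValueError(
                f"solution_volume must be > 0 mL, got {self.solution_volume}"
            )


@dataclass
class FidRecord:
    """Complex time-domain free induction decay with acquisition metadata."""

    points: np.ndarray
    dwell_time: float  # seconds per complex point
    spectrometer_freq: float  # MHz
    scans: int = 1
    receiver_gain: float = 1.0
    series_id: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=complex)
        if self.points.size == 0:
            raise ValueError("FID must contain at least one point")
        if not self.dwell_time > 0:
            raise ValueError(f"dwell_time must be > 0 s, got {self.dwell_time}")
        if not self.spectrometer_freq > 0:
            raise ValueError(
                f"spectrometer_freq must be > 0 MHz, got {self.spectrometer_freq}"
            )

    @property
    def sweep_width_hz(self) -> float:
        return 1.0 / self.dwell_time

    @property
    def acquisition_time(self) -> float:
        return self.points.size * self.dwell_time


@dataclass
class Spectrum1D:
    """Frequency-domain real spectrum on a descending ppm axis.

    ``intensity`` is the absorptive (real) part; ``intensity_imag`` keeps the
    dispersive part when available so phase correction can be (re)applied.
    ``processing_log`` records every operation applied, in order.
    """

    ppm_axis: np.ndarray
    intensity: np.ndarray
    spectrometer_freq: float  # MHz
    scans: int = 1
    receiver_gain: float = 1.0
    prep: Optional[SamplePrep] = None
    series_id: str = ""
    sample_id: str = ""
    processing_log: list = field(default_factory=list)
    intensity_imag: Optional[np.ndarray] = None
    unreferenced: bool = False  # set when TMS referencing failed

    def __post_init__(self) -> None:
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity_imag is not None:
            self.intensity_imag = np.asarray(self.intensity_imag, dtype=float)
            if self.intensity_imag.shape != self.intensity.shape:
                raise ValueError("intensity_imag must match intensity shape")
        if self.ppm_axis.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("ppm_axis and intensity must be 1-D")
        if self.ppm_axis.size != self.intensity.size:
            raise ValueError(
                f"axis/intensity length mismatch: {self.ppm_axis.size} vs "
                f"{self.intensity.size}"
            )
        if self.ppm_axis.size < 2:
            raise ValueError("spectrum needs at least two points")
        steps = np.diff(self.ppm_axis)
        if not (np.all(steps < 0) or np.all(steps > 0)):
            raise ValueError("ppm_axis must be strictly monotonic")
        mean_step = steps.mean()
        if not np.allclose(steps, mean_step, rtol=_GRID_RTOL, atol=0.0):
            # atol guard for axes crossing zero: compare against |mean step|
            if not np.all(np.abs(steps - mean_step) <= _GRID_RTOL * abs(mean_step) + 1e-15):
                raise ValueError("ppm_axis spacing is not constant")
        if not self.spectrometer_freq > 0:
            raise ValueError(
                f"spectrometer_freq must be > 0 MHz, got {self.spectrometer_freq}"
            )

    @property
    def step(self) -> float:
        """Absolute grid spacing in ppm."""
        return abs(float(self.ppm_axis[1] - self.ppm_axis[0]))

    @property
    def descending(self) -> bool:
        return bool(self.ppm_axis[0] > self.ppm_axis[-1])

    def copy(self, **changes) -> "Spectrum1D":
        """Shallow copy with field overrides; arrays are duplicated."""
        out = replace(self, **changes)
        if "ppm_axis" not in changes:
            out.ppm_axis = self.ppm_axis.copy()
        if "intensity" not in changes:
            out.intensity = self.intensity.copy()
        if "intensity_imag" not in changes and self.intensity_imag is not None:
            out.intensity_imag = self.intensity_imag.copy()
        out.processing_log = list(self.processing_log)
        return out

    def log(self, entry: str) -> None:
        self.processing_log.append(entry)
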