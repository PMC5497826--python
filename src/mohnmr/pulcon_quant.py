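"""PULCON/ERETIC quantification core.

Calibration: for each of the four quantref signals

    ERETIC_i = I_i * MW / (C * N_i)

with I the absolute integral, MW the molecular weight, C the concentration
in g/L and N the number of protons behind the signal; the series factor is
the arithmetic mean of the four.  Sample concentrations invert the relation:

    C = I * MW / (ERETIC * N)

Mass fractions follow from the sample-prep dilution (mass in mg, volume in
mL), reported in g/100 g.  The integral convention is a plain Riemann sum
(intensity × ppm step) — any consistent convention cancels in PULCON.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from .model import SamplePrep, Spectrum1D
from .processing import DEFAULT_NOISE_REGION, noise_sd

__all__ = [
    "IntegrationRegion",
    "EreticFactor",
    "QuantResult",
    "QuantrefRecipe",
    "CalibrationError",
    "QuantificationError",
    "load_region_scheme",
    "default_region_scheme",
    "region_mask",
    "integrate_region",
    "eretic_from_quantref",
    "quantify",
    "to_mass_fraction",
    "quantify_pah4",
    "detect_peak",
    "estimate_lod",
    "LOD_REF_HWHM_PPM",
]

log = logging.getLogger(__name__)

ROLES = ("mosh", "moah", "other", "pah4", "quantref_signal", "control")

#: half width at half maximum (ppm) of the synthetic reference line used to
#: convert a 3×noise-SD peak height into a limit of detection (≈1 Hz at
#: 400 MHz, a typical well-shimmed narrow multiplet line)
LOD_REF_HWHM_PPM = 0.0025

PAH4_ANALYTES = (
    "benz_a_anthracene",
    "benzo_a_pyrene",
    "chrysene",
    "benzo_b_fluoranthene",
)

QUANTREF_SIGNALS = ("tcnb_s", "ethylbenzene_m", "ethylbenzene_q", "ethylbenzene_t")


class CalibrationError(RuntimeError):
    """Quantref integration produced an unusable ERETIC factor."""


class QuantificationError(RuntimeError):
    """Quantification refused (invalid or missing calibration)."""


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IntegrationRegion:
    """Named set of ppm windows with exclusions, bound to a reference compound.

    ``windows`` and ``exclusions`` are (high_ppm, low_ppm) pairs; every
    exclusion must lie inside the union of windows.
    """

    name: str
    windows: Tuple[Tuple[float, float], ...]
    ref_compound: str
    ref_mw: float
    n_protons: int
    role: str
    exclusions: Tuple[Tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "windows", tuple((float(h), float(l)) for h, l in self.windows)
        )
        object.__setattr__(
            self, "exclusions",
            tuple((float(h), float(l)) for h, l in self.exclusions),
        )
        for high, low in self.windows + self.exclusions:
            if not high > low:
                raise ValueError(
                    f"{self.name}: window ({high}, {low}) must have high > low"
                )
        for eh, el in self.exclusions:
            if not any(h >= eh and l <= el for h, l in self.windows):
                raise ValueError(
                    f"{self.name}: exclusion ({eh}, {el}) not inside any window"
                )
        if self.n_protons < 1:
            raise ValueError(f"{self.name}: n_protons must be >= 1")
        if not self.ref_mw > 0:
            raise ValueError(f"{self.name}: ref_mw must be > 0")
        if self.role not in ROLES:
            raise ValueError(f"{self.name}: unknown role {self.role!r}")

    @property
    def total_width(self) -> float:
        """Summed included width in ppm (exclusions subtracted)."""
        w = sum(h - l for h, l in self.windows)
        w -= sum(h - l for h, l in self.exclusions)
        return w


def load_region_scheme(path: Optional[str] = None) -> Dict[str, IntegrationRegion]:
    """Load a region scheme from YAML (the packaged default when *path* is
    None)."""
    if path is None:
        text = (resources.files("mohnmr") / "data" / "regions.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    scheme: Dict[str, IntegrationRegion] = {}
    for name, entry in doc["regions"].items():
        scheme[name] = IntegrationRegion(
            name=name,
            windows=tuple(tuple(w) for w in entry["windows"]),
            exclusions=tuple(tuple(e) for e in entry.get("exclusions", ())),
            ref_compound=entry["ref_compound"],
            ref_mw=float(entry["ref_mw"]),
            n_protons=int(entry["n_protons"]),
            role=entry["role"],
        )
    return scheme


def scheme_version(path: Optional[str] = None) -> str:
    if path is None:
        text = (resources.files("mohnmr") / "data" / "regions.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return str(yaml.safe_load(text).get("scheme_version", "unversioned"))


_DEFAULT_SCHEME: Optional[Dict[str, IntegrationRegion]] = None


def default_region_scheme() -> Dict[str, IntegrationRegion]:
    global _DEFAULT_SCHEME
    if _DEFAULT_SCHEME is None:
        _DEFAULT_SCHEME = load_region_scheme()
    return _DEFAULT_SCHEME


def region_mask(ppm_axis: np.ndarray, region: IntegrationRegion) -> np.ndarray:
    """Boolean mask of grid points inside the region.

    Windows and exclusions are half-open ``(low, high]`` so adjacent windows
    partition the axis without double-counting.
    """
    mask = np.zeros(ppm_axis.shape, dtype=bool)
    for high, low in region.windows:
        mask |= (ppm_axis > low) & (ppm_axis <= high)
    for high, low in region.exclusions:
        mask &= ~((ppm_axis > low) & (ppm_axis <= high))
    return mask


def integrate_region(spec: Spectrum1D, region: IntegrationRegion) -> float:
    """Absolute integral over the region: Σ intensity × |Δppm|."""
    lo, hi = float(spec.ppm_axis.min()), float(spec.ppm_axis.max())
    for high, low in region.windows:
        if high > hi + spec.step or low < lo - spec.step:
            raise ValueError(
                f"region {region.name!r} window ({high}, {low}) outside axis "
                f"range [{lo:.3f}, {hi:.3f}]"
            )
    mask = region_mask(spec.ppm_axis, region)
    if not mask.any():
        warnings.warn(
            f"region {region.name!r} covers no grid points (fully excluded?)",
            stacklevel=2,
        )
        return 0.0
    return float(np.sum(spec.intensity[mask]) * spec.step)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuantrefRecipe:
    """Composition of the calibration sample (g/L per compound).

    Default: 50 mg tetrachloronitrobenzene + 50 mg ethylbenzene in 10 mL of
    CDCl3, i.e. 5.0 g/L each.
    """

    tcnb_conc: float = 5.0
    ethylbenzene_conc: float = 5.0

    def concentration_for(self, region: IntegrationRegion) -> float:
        if region.ref_compound == "tetrachloronitrobenzene":
            return self.tcnb_conc
        if region.ref_compound == "ethylbenzene":
            return self.ethylbenzene_conc
        raise KeyError(f"no recipe concentration for {region.ref_compound!r}")


@dataclass(frozen=True)
class EreticFactor:
    """Series-level PULCON calibration constant.

    ``value`` is the arithmetic mean of the four per-signal factors; units
    are (arbitrary integral units)·(g/mol) / ((g/L)·proton).
    """

    value: float
    per_signal: Dict[str, float]
    series_id: str = ""
    valid: bool = True

    def __post_init__(self) -> None:
        if self.per_signal:
            mean = sum(self.per_signal.values()) / len(self.per_signal)
            if not math.isclose(self.value, mean, rel_tol=1e-12):
                raise ValueError("value must equal the mean of per_signal factors")
            if any(v <= 0 for v in self.per_signal.values()):
                raise ValueError("per-signal factors must be positive")

    @property
    def spread(self) -> float:
        """Relative per-signal spread, max/min − 1."""
        vals = list(self.per_signal.values())
        return max(vals) / min(vals) - 1.0 if vals else 0.0


def eretic_from_quantref(
    spec: Spectrum1D,
    recipe: Optional[QuantrefRecipe] = None,
    scheme: Optional[Dict[str, IntegrationRegion]] = None,
    spread_tolerance: float = 0.10,
) -> EreticFactor:
    """Compute the series ERETIC factor from a quantref spectrum.

    Integrates the four quantref signals, converts each to a per-signal
    factor and averages.  The factor is flagged invalid when the relative
    spread between signals exceeds ``spread_tolerance``.
    """
    recipe = recipe or QuantrefRecipe()
    scheme = scheme or default_region_scheme()
    per_signal: Dict[str, float] = {}
    for name in QUANTREF_SIGNALS:
        region = scheme[name]
        integral = integrate_region(spec, region)
        if integral <= 0:
            raise CalibrationError(
                f"quantref signal {name!r} has non-positive integral "
                f"({integral:.4g}); calibration aborted"
            )
        conc = recipe.concentration_for(region)
        per_signal[name] = integral * region.ref_mw / (conc * region.n_protons)
    value = sum(per_signal.values()) / len(per_signal)
    spread = max(per_signal.values()) / min(per_signal.values()) - 1.0
    valid = spread <= spread_tolerance
    if not valid:
        log.warning(
            "ERETIC per-signal spread %.1f%% exceeds %.0f%% tolerance; "
            "factor flagged invalid", 100 * spread, 100 * spread_tolerance,
        )
    return EreticFactor(value=value, per_signal=per_signal,
                        series_id=spec.series_id, valid=valid)


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuantResult:
    """Quantification outcome for one analyte/region."""

    analyte: str
    absolute_integral: float
    concentration: float  # g/L
    mass_fraction: Optional[float] = None  # g/100 g
    lod_mass_fraction: Optional[float] = None  # g/100 g
    detected: bool = True
    unconvertible: bool = False  # prep missing, mass fraction unavailable

    def format_mass_fraction(self, decimals: int = 2) -> str:
        """Table-style rendering: value, or ``n.d. <LOD`` when undetected."""
        if not self.detected:
            lod = self.lod_mass_fraction
            return f"n.d. <{lod:.{decimals}f}" if lod is not None else "n.d."
        if self.unconvertible or self.mass_fraction is None:
            return "n/a"
        return f"{self.mass_fraction:.{decimals}f}"


def quantify(
    spec: Spectrum1D,
    region: IntegrationRegion,
    eretic: EreticFactor,
    require_valid: bool = True,
) -> QuantResult:
    """Concentration of a region's analyte in g/L via the PULCON relation."""
    if eretic is None:
        raise QuantificationError("no ERETIC factor supplied")
    if require_valid and not eretic.valid:
        raise QuantificationError(
            "ERETIC factor is flagged invalid (per-signal spread too large); "
            "pass require_valid=False to override"
        )
    integral = integrate_region(spec, region)
    conc = integral * region.ref_mw / (eretic.value * region.n_protons)
    # noise can push a near-empty region's integral below zero; clamp
    return QuantResult(
        analyte=region.name,
        absolute_integral=integral,
        concentration=max(conc, 0.0),
    )


def to_mass_fraction(result: QuantResult, prep: Optional[SamplePrep]) -> QuantResult:
    """Convert a concentration (g/L) to g analyte / 100 g sample.

    mass_fraction = C · (V[mL]/1000) / (m[mg]/1000) · 100
    """
    if prep is None:
        return replace(result, unconvertible=True)
    mf = result.concentration * (prep.solution_volume / 1000.0) / (
        prep.sample_mass / 1000.0
    ) * 100.0
    return replace(result, mass_fraction=mf, unconvertible=False)


def _dilution_factor(prep: SamplePrep) -> float:
    """g/100 g per (g/L)."""
    return prep.solution_volume / prep.sample_mass * 100.0


def estimate_lod(
    spec: Spectrum1D,
    region: IntegrationRegion,
    eretic: EreticFactor,
    prep: Optional[SamplePrep],
    noise_region: Tuple[float, float] = DEFAULT_NOISE_REGION,
    ref_hwhm_ppm: float = LOD_REF_HWHM_PPM,
) -> float:
    """Limit of detection in g/100 g for the region's analyte.

    The LOD is the mass fraction of a synthetic Lorentzian reference line
    (HWHM ``ref_hwhm_ppm``) whose peak height equals 3× the noise SD:
    its area is π · height · HWHM, converted through eq. 2 and the dilution.
    """
    sd = noise_sd(spec, noise_region)
    if sd == 0.0:
        warnings.warn(
            "zero noise estimate; LOD reported as 0", stacklevel=2
        )
        return 0.0
    lod_integral = math.pi * (3.0 * sd) * ref_hwhm_ppm
    lod_conc = lod_integral * region.ref_mw / (eretic.value * region.n_protons)
    if prep is None:
        raise ValueError("sample prep required to express LOD in g/100 g")
    return lod_conc * _dilution_factor(prep)


def _boxcar(y: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return y
    kernel = np.full(width, 1.0 / width)
    return np.convolve(y, kernel, mode="same")


def detect_peak(
    spec: Spectrum1D,
    region: IntegrationRegion,
    noise_region: Tuple[float, float] = DEFAULT_NOISE_REGION,
    ref_hwhm_ppm: float = LOD_REF_HWHM_PPM,
) -> Tuple[float, float, bool]:
    """3×noise-SD height criterion for a peak inside the region's windows.

    Height and noise SD are both measured after boxcar smoothing matched to
    the reference linewidth (~2×HWHM) — the raw pointwise maximum of a few
    hundred noise samples would exceed 3σ far too often for the criterion to
    mean anything.  Returns ``(height, threshold, detected)``; the boundary
    is inclusive (height == threshold counts as detected).
    """
    width = max(1, int(round(2.0 * ref_hwhm_ppm / spec.step)))
    smooth = _boxcar(spec.intensity, width)
    mask = region_mask(spec.ppm_axis, region)
    if mask.any():
        # a PAH window can sit on the MOAH hump: measure height above the
        # local (quadratic) background, not above zero
        xw, yw = spec.ppm_axis[mask], smooth[mask]
        if xw.size >= 5:
            coeffs = np.polyfit(xw - xw.mean(), yw, 2)
            yw = yw - np.polyval(coeffs, xw - xw.mean())
        height = float(yw.max())
    else:
        height = 0.0
    high, low = max(noise_region), min(noise_region)
    nmask = (spec.ppm_axis > low) & (spec.ppm_axis <= high)
    sd = float(np.std(smooth[nmask])) if nmask.any() else 0.0
    threshold = 3.0 * sd
    return height, threshold, height >= threshold


def quantify_pah4(
    spec: Spectrum1D,
    eretic: EreticFactor,
    prep: Optional[SamplePrep],
    scheme: Optional[Dict[str, IntegrationRegion]] = None,
    noise_region: Tuple[float, float] = DEFAULT_NOISE_REGION,
    require_valid: bool = True,
) -> List[QuantResult]:
    """Targeted quantification of the four PAH4 marker compounds.

    Detection: the smoothed peak height inside the analyte's window must
    reach 3× the noise SD (see :func:`detect_peak`; boundary inclusive);
    otherwise the result is flagged not-detected and carries its LOD.
    """
    scheme = scheme or default_region_scheme()
    results: List[QuantResult] = []
    for name in PAH4_ANALYTES:
        region = scheme[name]
        res = quantify(spec, region, eretic, require_valid=require_valid)
        res = to_mass_fraction(res, prep)
        _, _, detected = detect_peak(spec, region, noise_region)
        lod = (
            estimate_lod(spec, region, eretic, prep, noise_region)
            if prep is not None else None
        )
        results.append(replace(res, detected=detected, lod_mass_fraction=lod))
    return results
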