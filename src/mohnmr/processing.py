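"""FID → referenced, phased, baseline-corrected absorptive spectrum.

All operations are deterministic and append to ``processing_log``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import optimize, sparse
from scipy.sparse.linalg import splu

from .model import FidRecord, Spectrum1D

__all__ = [
    "ProcessingConfig",
    "fourier_transform",
    "phase_correct",
    "baseline_correct",
    "reference_to_tms",
    "noise_sd",
    "process_fid",
]

#: default signal-free window used for noise estimates (high, low) ppm
DEFAULT_NOISE_REGION = (10.5, 9.5)


@dataclass
class ProcessingConfig:
    """Knobs for the FID-to-spectrum pipeline.

    ``line_broadening`` is exponential apodization in Hz; ``zero_fill_factor``
    multiplies the (power-of-two-padded) FID length.  Baseline defaults to
    asymmetric least squares with a smoothness scale chosen so features
    broader than ~0.5 ppm survive as signal.
    """

    line_broadening: float = 0.3
    zero_fill_factor: int = 2
    phase_method: str = "auto"  # auto | manual
    manual_ph0: float = 0.0
    manual_ph1: float = 0.0
    baseline_method: str = "asymmetric-least-squares"  # or iterative-polynomial
    baseline_smoothness_ppm: float = 2.0
    baseline_asymmetry: float = 1e-3
    baseline_niter: int = 10
    baseline_poly_degree: int = 4
    reference_shift: float = 0.0
    reference_search_window: float = 0.3
    noise_region: Tuple[float, float] = DEFAULT_NOISE_REGION

    def __post_init__(self) -> None:
        if self.line_broadening < 0:
            raise ValueError("line_broadening must be >= 0 Hz")
        if self.zero_fill_factor not in (1, 2, 4):
            raise ValueError("zero_fill_factor must be one of {1, 2, 4}")
        if self.phase_method not in ("auto", "manual"):
            raise ValueError("phase_method must be 'auto' or 'manual'")


def _next_pow2(n: int) -> int:
    return 1 << (n - 1).bit_length()


def noise_sd(spec: Spectrum1D, region: Tuple[float, float] = DEFAULT_NOISE_REGION) -> float:
    """Standard deviation of intensity in a signal-free ppm window."""
    high, low = max(region), min(region)
    mask = (spec.ppm_axis > low) & (spec.ppm_axis <= high)
    if not mask.any():
        return 0.0
    return float(np.std(spec.intensity[mask]))


# ---------------------------------------------------------------------------
# Fourier transform
# ---------------------------------------------------------------------------


def fourier_transform(fid: FidRecord, cfg: Optional[ProcessingConfig] = None) -> Spectrum1D:
    """Apodize, zero-fill, FFT and phase an FID into a ppm-axis spectrum.

    The transform is scaled by the dwell time so peak areas (intensity × Hz)
    approximate the continuous-time Fourier integral: a unit-amplitude
    exponentially decaying complex sinusoid transforms to an absorptive
    Lorentzian of area 1/2.
    """
    cfg = cfg or ProcessingConfig()
    n = fid.points.size
    t = np.arange(n) * fid.dwell_time
    data = fid.points * np.exp(-np.pi * cfg.line_broadening * t)
    data = data.copy()
    data[0] *= 0.5  # half first point: suppresses the DC baseline offset
    nfft = _next_pow2(n) * cfg.zero_fill_factor
    z = np.fft.fftshift(np.fft.fft(data, n=nfft)) * fid.dwell_time
    freqs = np.fft.fftshift(np.fft.fftfreq(nfft, d=fid.dwell_time))
    ppm = freqs / fid.spectrometer_freq  # Hz / MHz
    # store descending
    ppm, z = ppm[::-1].copy(), z[::-1].copy()
    spec = Spectrum1D(
        ppm_axis=ppm, intensity=z.real, intensity_imag=z.imag,
        spectrometer_freq=fid.spectrometer_freq, scans=fid.scans,
        receiver_gain=fid.receiver_gain, series_id=fid.series_id,
        sample_id=fid.sample_id,
    )
    spec.log(f"fourier_transform:lb={cfg.line_broadening}Hz,nfft={nfft}")
    if cfg.phase_method == "manual":
        return _apply_phase(spec, cfg.manual_ph0, cfg.manual_ph1)
    return phase_correct(spec, cfg)


# ---------------------------------------------------------------------------
# phasing
# ---------------------------------------------------------------------------


def _apply_phase(spec: Spectrum1D, ph0: float, ph1: float) -> Spectrum1D:
    if spec.intensity_imag is None:
        raise ValueError("phase correction needs the imaginary part")
    frac = np.linspace(0.0, 1.0, spec.intensity.size)
    phi = np.deg2rad(ph0 + ph1 * frac)
    z = (spec.intensity + 1j * spec.intensity_imag) * np.exp(-1j * phi)
    out = spec.copy(intensity=z.real, intensity_imag=z.imag)
    out.log(f"phase:ph0={ph0:.3f},ph1={ph1:.3f}")
    return out


def _neg_penalty(spec: Spectrum1D, ph0: float, ph1: float) -> float:
    frac = np.linspace(0.0, 1.0, spec.intensity.size)
    phi = np.deg2rad(ph0 + ph1 * frac)
    re = spec.intensity * np.cos(phi) + spec.intensity_imag * np.sin(phi)
    re = re - np.median(re)
    return float(np.sum(np.maximum(0.0, -re)))


def phase_correct(spec: Spectrum1D, cfg: Optional[ProcessingConfig] = None) -> Spectrum1D:
    """Automatic phase correction.

    Minimizes the summed negative intensity (after median-offset removal)
    over zero- and first-order phase.  Falls back to a zero-order-only grid
    search if the simplex refinement fails; ties are broken toward 0°.
    """
    cfg = cfg or ProcessingConfig()
    if spec.intensity_imag is None:
        raise ValueError("phase correction needs the imaginary part")
    # coarse zero-order grid, starting at 0 so exact ties keep phase 0
    grid = np.arange(0.0, 360.0, 5.0)
    scores = [_neg_penalty(spec, g, 0.0) for g in grid]
    best0 = float(grid[int(np.argmin(scores))])
    if best0 > 180.0:
        best0 -= 360.0
    scale = max(float(np.max(np.abs(spec.intensity))), 1e-300)

    def objective(p):
        # tiny pull toward 0° so degenerate inputs stay unphased
        return _neg_penalty(spec, p[0], p[1]) + 1e-10 * scale * (
            abs(p[0]) + abs(p[1])
        )

    res = optimize.minimize(
        objective, x0=[best0, 0.0], method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-12 * scale, "maxiter": 2000},
    )
    if res.success:
        ph0, ph1 = float(res.x[0]), float(res.x[1])
    else:  # pragma: no cover - defensive fallback
        import logging
        logging.getLogger(__name__).warning(
            "phase optimizer did not converge; falling back to ph0-only grid"
        )
        fine = np.arange(best0 - 5.0, best0 + 5.0, 0.05)
        ph0 = float(fine[int(np.argmin([_neg_penalty(spec, g, 0.0) for g in fine]))])
        ph1 = 0.0
    ph0 = (ph0 + 180.0) % 360.0 - 180.0
    return _apply_phase(spec, ph0, ph1)


# ---------------------------------------------------------------------------
# baseline
# ---------------------------------------------------------------------------


def _asls_baseline(y: np.ndarray, lam: float, p: float, niter: int) -> np.ndarray:
    """Asymmetric-least-squares baseline (Whittaker smoother, asymmetric w)."""
    n = y.size
    d = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    dtd = (lam * (d.T @ d)).tocsc()
    w = np.ones(n)
    z = y
    for _ in range(niter):
        wmat = sparse.diags(w, 0, format="csc")
        z = splu((wmat + dtd).tocsc()).solve(w * y)
        wnew = np.where(y > z, p, 1.0 - p)
        if np.array_equal(wnew, w):
            break
        w = wnew
    return z


def _modpoly_baseline(y: np.ndarray, degree: int, niter: int) -> np.ndarray:
    """Iterative polynomial baseline (clip-to-fit)."""
    x = np.linspace(-1.0, 1.0, y.size)
    work = y.copy()
    fit = np.zeros_like(y)
    for _ in range(niter):
        coeffs = np.polynomial.polynomial.polyfit(x, work, degree)
        fit = np.polynomial.polynomial.polyval(x, coeffs)
        work = np.minimum(work, fit)
    return fit


def baseline_correct(spec: Spectrum1D, cfg: Optional[ProcessingConfig] = None) -> Spectrum1D:
    """Subtract a smooth baseline from the real spectrum.

    With the default asymmetric-least-squares method the smoothness penalty
    is scaled so only features broader than ``baseline_smoothness_ppm`` are
    followed by the baseline — the broad MOSH/MOAH humps are left intact.
    """
    cfg = cfg or ProcessingConfig()
    y = spec.intensity
    if cfg.baseline_method == "iterative-polynomial":
        base = _modpoly_baseline(y, cfg.baseline_poly_degree,
                                 max(cfg.baseline_niter, 20))
        method = f"modpoly:deg={cfg.baseline_poly_degree}"
    else:
        pts_per_ppm = 1.0 / spec.step
        # Whittaker smoother cutoff wavelength scales as lam^(1/4) points
        lam = (cfg.baseline_smoothness_ppm * pts_per_ppm) ** 4
        base = _asls_baseline(y, lam, cfg.baseline_asymmetry, cfg.baseline_niter)
        method = f"asls:smooth={cfg.baseline_smoothness_ppm}ppm"
    corrected = y - base
    sd = noise_sd(spec.copy(intensity=corrected), cfg.noise_region)
    signal_frac = float(np.mean(np.abs(corrected) > 3 * sd)) if sd > 0 else 0.0
    if signal_frac > 0.5:
        import logging
        logging.getLogger(__name__).warning(
            ">50%% of points classified as signal (%.0f%%); baseline estimate "
            "may be unreliable", 100 * signal_frac,
        )
    out = spec.copy(intensity=corrected)
    out.log(f"baseline_correct:{method}")
    return out


# ---------------------------------------------------------------------------
# referencing
# ---------------------------------------------------------------------------


def reference_to_tms(spec: Spectrum1D, cfg: Optional[ProcessingConfig] = None) -> Spectrum1D:
    """Shift the ppm axis so the TMS singlet maximum sits at the reference
    shift (default 0.00 ppm).

    If no peak at least 3 noise-SD high is found within the search window the
    spectrum is returned unchanged with ``unreferenced`` set.
    """
    cfg = cfg or ProcessingConfig()
    win = cfg.reference_search_window
    mask = (spec.ppm_axis >= cfg.reference_shift - win) & (
        spec.ppm_axis <= cfg.reference_shift + win
    )
    out = spec.copy()
    if not mask.any():
        out.unreferenced = True
        out.log("reference_to_tms:failed(no-window)")
        return out
    sd = noise_sd(spec, cfg.noise_region)
    local = spec.intensity[mask]
    peak_idx = int(np.argmax(local))
    height = local[peak_idx] - np.median(local)
    threshold = 3.0 * sd if sd > 0 else 0.0
    if height <= threshold:
        out.unreferenced = True
        out.log("reference_to_tms:failed(no-peak)")
        return out
    peak_ppm = float(spec.ppm_axis[mask][peak_idx])
    shift = cfg.reference_shift - peak_ppm
    out.ppm_axis = spec.ppm_axis + shift
    out.unreferenced = False
    out.log(f"reference_to_tms:shift={shift:+.6f}ppm")
    return out


def process_fid(fid: FidRecord, cfg: Optional[ProcessingConfig] = None) -> Spectrum1D:
    """Full chain: FT (incl. phasing) → baseline → TMS referencing."""
    cfg = cfg or ProcessingConfig()
    spec = fourier_transform(fid, cfg)
    spec = baseline_correct(spec, cfg)
    return reference_to_tms(spec, cfg)
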