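import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mohnmr import pulcon_quant as pq
from mohnmr import synth
from mohnmr.model import SamplePrep, Spectrum1D
from tests.conftest import PREP, SMALL_GRID, discrete_sample

SFO = 400.13


def _flat_spectrum(n=32768, value=0.0):
    axis = np.linspace(12.0, -2.0, n)
    return Spectrum1D(ppm_axis=axis, intensity=np.full(n, value),
                      spectrometer_freq=SFO)


# ---------------------------------------------------------------------------
# region scheme
# ---------------------------------------------------------------------------


def test_default_scheme_windows(scheme):
    assert scheme["mosh"].windows == ((3.0, 0.2),)
    assert scheme["mosh"].exclusions == ((1.58, 1.50),)
    assert scheme["mosh"].ref_mw == 138.25
    assert scheme["mosh"].n_protons == 18
    assert scheme["moah"].windows == (
        (9.20, 7.55), (7.50, 7.30), (7.22, 7.00), (6.97, 6.50)
    )
    assert scheme["moah"].total_width == pytest.approx(2.54)
    assert scheme["other"].ref_mw == 92.09
    assert scheme["chrysene"].windows == ((8.76, 8.70),)
    assert scheme["benzo_a_pyrene"].ref_mw == 252.32
    assert scheme["control_cyclohexane"].n_protons == 12


def test_region_validation_errors():
    with pytest.raises(ValueError, match="high > low"):
        pq.IntegrationRegion("bad", ((1.0, 2.0),), "x", 100.0, 1, "mosh")
    with pytest.raises(ValueError, match="not inside"):
        pq.IntegrationRegion("bad", ((2.0, 1.0),), "x", 100.0, 1, "mosh",
                             exclusions=((5.0, 4.0),))
    with pytest.raises(ValueError, match="n_protons"):
        pq.IntegrationRegion("bad", ((2.0, 1.0),), "x", 100.0, 0, "mosh")


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def test_lorentzian_against_arctan_closed_form(scheme):
    # unit-area Lorentzian, HWHM γ=0.0025, centered at δ 1.0; expected
    # in-window fraction from the Lorentzian CDF (1/π)·arctan(Δ/γ)
    n = 65536
    axis = np.linspace(12.0, -2.0, n)
    gamma = 0.0025
    y = (gamma / math.pi) / ((axis - 1.0) ** 2 + gamma**2)
    spec = Spectrum1D(ppm_axis=axis, intensity=y, spectrometer_freq=SFO)
    got = pq.integrate_region(spec, scheme["mosh"])
    cdf = lambda d: math.atan(d / gamma) / math.pi
    expected = (cdf(3.0 - 1.0) + cdf(1.0 - 0.2)) - (cdf(0.58) - cdf(0.50))
    assert expected == pytest.approx(0.998, abs=5e-4)  # spec's stated value
    assert got == pytest.approx(expected, rel=2e-3)


def test_zero_spectrum_integrates_to_zero(scheme):
    assert pq.integrate_region(_flat_spectrum(), scheme["mosh"]) == 0.0


def test_moah_windows_partition_envelope(scheme):
    rng = np.random.default_rng(1)
    n = 32768
    axis = np.linspace(12.0, -2.0, n)
    spec = Spectrum1D(ppm_axis=axis, intensity=rng.normal(size=n),
                      spectrometer_freq=SFO)

    def region(*windows):
        return pq.IntegrationRegion("tmp", tuple(windows), "x", 1.0, 1, "moah")

    whole = pq.integrate_region(spec, region((9.20, 6.50)))
    parts = pq.integrate_region(spec, scheme["moah"])
    cutouts = pq.integrate_region(
        spec, region((7.55, 7.50), (7.30, 7.22), (7.00, 6.97))
    )
    assert parts + cutouts == pytest.approx(whole, rel=1e-9, abs=1e-9)


def test_region_outside_axis_raises(scheme):
    axis = np.linspace(5.0, 0.0, 1024)
    spec = Spectrum1D(ppm_axis=axis, intensity=np.zeros(1024),
                      spectrometer_freq=SFO)
    with pytest.raises(ValueError, match="outside axis"):
        pq.integrate_region(spec, scheme["moah"])


def test_fully_excluded_window_warns():
    region = pq.IntegrationRegion(
        "hole", ((2.0, 1.0),), "x", 1.0, 1, "mosh",
        exclusions=((2.0, 1.0),),
    )
    spec = _flat_spectrum(value=1.0)
    with pytest.warns(UserWarning, match="no grid points"):
        assert pq.integrate_region(spec, region) == 0.0


def test_no_double_counting_across_sum_regions(scheme):
    spec = _flat_spectrum()
    masks = [pq.region_mask(spec.ppm_axis, scheme[name])
             for name in ("mosh", "moah", "other")]
    total = sum(int(m.sum()) for m in masks)
    union = int(np.logical_or.reduce(masks).sum())
    assert total == union  # disjoint point sets


# ---------------------------------------------------------------------------
# ERETIC factor
# ---------------------------------------------------------------------------


def test_eretic_direct_evaluation(scheme):
    # rectangles with known integrals; the ethylbenzene quartet gets
    # I = 1500 → factor 1500·106.17/(5.0·2) = 15925.5
    spec = _flat_spectrum()
    target = 15925.5
    for name in pq.QUANTREF_SIGNALS:
        region = scheme[name]
        conc = 5.0
        integral = target * conc * region.n_protons / region.ref_mw
        mask = pq.region_mask(spec.ppm_axis, region)
        spec.intensity[mask] = integral / (mask.sum() * spec.step)
    eretic = pq.eretic_from_quantref(spec)
    assert eretic.per_signal["ethylbenzene_q"] == pytest.approx(15925.5, rel=1e-9)
    assert eretic.value == pytest.approx(15925.5, rel=1e-9)
    assert eretic.valid


def test_eretic_consistent_quantref_spread(quantref_clean):
    eretic = pq.eretic_from_quantref(quantref_clean)
    assert eretic.spread < 1e-6
    assert eretic.value == pytest.approx(synth.AREA_SCALE, rel=1e-9)


def test_eretic_scales_linearly(quantref_clean):
    doubled = quantref_clean.copy(intensity=quantref_clean.intensity * 2.0)
    e1 = pq.eretic_from_quantref(quantref_clean)
    e2 = pq.eretic_from_quantref(doubled)
    assert e2.value == pytest.approx(2.0 * e1.value, rel=1e-12)


def test_eretic_nonpositive_integral_is_calibration_error():
    spec = _flat_spectrum(value=0.0)
    with pytest.raises(pq.CalibrationError, match="non-positive"):
        pq.eretic_from_quantref(spec)


def test_eretic_spread_flags_invalid(quantref_clean, scheme):
    spec = quantref_clean.copy()
    mask = pq.region_mask(spec.ppm_axis, scheme["tcnb_s"])
    spec.intensity[mask] *= 1.5  # break one signal by 50%
    eretic = pq.eretic_from_quantref(spec)
    assert not eretic.valid
    with pytest.raises(pq.QuantificationError):
        pq.quantify(spec, scheme["mosh"], eretic)
    pq.quantify(spec, scheme["mosh"], eretic, require_valid=False)


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------


def test_quantify_formula(scheme):
    eretic = pq.EreticFactor(value=15925.5, per_signal={"a": 15925.5})
    spec = _flat_spectrum()
    region = scheme["moah"]
    k = 2.5
    mask = pq.region_mask(spec.ppm_axis, region)
    spec.intensity[mask] = 15925.5 * k / (mask.sum() * spec.step)
    res = pq.quantify(spec, region, eretic)
    assert res.concentration == pytest.approx(k * 128.17 / 8.0, rel=1e-9)


def test_eq1_eq2_roundtrip(quantref_clean, scheme):
    eretic = pq.eretic_from_quantref(quantref_clean)
    res = pq.quantify(quantref_clean, scheme["ethylbenzene_q"], eretic)
    assert res.concentration == pytest.approx(5.0, rel=1e-9)


@settings(max_examples=25, deadline=None)
@given(k=st.floats(min_value=1e-6, max_value=1e6))
def test_roundtrip_scale_invariant(k):
    # build once at module scope would leak between examples; cheap enough
    recipe = synth.SimulationRecipe(
        components=synth._quantref_components(),
        grid=(-2.0, 12.0, 8192), seed=11, artifacts=None,
    )
    spec, _ = synth.simulate_spectrum(recipe)
    spec.intensity *= k
    eretic = pq.eretic_from_quantref(spec)
    scheme = pq.default_region_scheme()
    res = pq.quantify(spec, scheme["ethylbenzene_t"], eretic)
    assert res.concentration == pytest.approx(5.0, rel=1e-9)


def test_zero_integral_zero_concentration(scheme, eretic_clean):
    res = pq.quantify(_flat_spectrum(), scheme["moah"], eretic_clean)
    assert res.concentration == 0.0


def test_mass_fraction_pure_sample():
    res = pq.QuantResult("mosh", 1.0, concentration=100.0 / 3.0)
    prep = SamplePrep(sample_mass=50.0, solution_volume=1.5)
    out = pq.to_mass_fraction(res, prep)
    assert out.mass_fraction == pytest.approx(100.0, rel=1e-4)


def test_mass_fraction_zero():
    out = pq.to_mass_fraction(pq.QuantResult("x", 0.0, 0.0), PREP)
    assert out.mass_fraction == 0.0


def test_mass_fraction_missing_prep_flagged():
    out = pq.to_mass_fraction(pq.QuantResult("x", 1.0, 1.0), None)
    assert out.unconvertible
    assert out.format_mass_fraction() == "n/a"


# ---------------------------------------------------------------------------
# PAH4 + LOD
# ---------------------------------------------------------------------------


def test_chrysene_spike_recovery(eretic_default, scheme):
    spec, ledger = synth.simulate_reference_solution(
        "chrysene", 0.55, seed=21, noise_sd=0.0, grid=SMALL_GRID
    )
    results = {r.analyte: r for r in pq.quantify_pah4(
        spec, eretic_default, spec.prep, scheme
    )}
    chry = results["chrysene"]
    assert chry.mass_fraction == pytest.approx(0.55, rel=0.03)


def test_blank_matrix_all_nd(eretic_default, scheme):
    spec, _ = synth.simulate_mineral_oil(
        100.0, 0.0, seed=8, noise_sd="calibrated", grid=SMALL_GRID
    )
    results = pq.quantify_pah4(spec, eretic_default, spec.prep, scheme)
    assert len(results) == 4
    for res in results:
        assert not res.detected
        assert res.lod_mass_fraction is not None
        assert res.lod_mass_fraction > 0
        assert res.format_mass_fraction().startswith("n.d. <")


def test_pah4_spike_detected(eretic_default, scheme):
    spec, _ = synth.simulate_mineral_oil(
        100.0, 0.6, pah4_spikes={"benz_a_anthracene": 0.5}, seed=9,
        noise_sd="calibrated", grid=SMALL_GRID,
    )
    results = {r.analyte: r for r in pq.quantify_pah4(
        spec, eretic_default, spec.prep, scheme
    )}
    assert results["benz_a_anthracene"].detected
    assert results["benz_a_anthracene"].mass_fraction == pytest.approx(0.5, rel=0.1)


def test_detection_boundary_inclusive(scheme):
    # degenerate exact-tie case: zero spectrum → height == threshold == 0
    spec = _flat_spectrum()
    height, threshold, detected = pq.detect_peak(spec, scheme["benz_a_anthracene"])
    assert height == threshold == 0.0
    assert detected  # boundary inclusive by the documented tie rule


def test_lod_scales_inversely_with_mass(eretic_default, scheme):
    spec, _ = synth.simulate_mineral_oil(
        100.0, 0.0, seed=8, noise_sd="calibrated", grid=SMALL_GRID
    )
    lod_full = pq.estimate_lod(spec, scheme["chrysene"], eretic_default,
                               SamplePrep(50.0, 1.5))
    lod_half = pq.estimate_lod(spec, scheme["chrysene"], eretic_default,
                               SamplePrep(25.0, 1.5))
    assert lod_half == pytest.approx(2.0 * lod_full, rel=1e-12)


def test_lod_zero_for_noise_free(eretic_default, scheme):
    # artifact-free: Lorentzian solvent tails would leave a tiny nonzero SD
    spec, _ = synth.simulate_mineral_oil(100.0, 0.0, seed=8, noise_sd=0.0,
                                         grid=SMALL_GRID, artifacts=None)
    with pytest.warns(UserWarning, match="zero noise"):
        lod = pq.estimate_lod(spec, scheme["chrysene"], eretic_default, PREP)
    assert lod == 0.0


# ---------------------------------------------------------------------------
# linearity / equivalents identity
# ---------------------------------------------------------------------------


def test_equivalents_identity_noise_free(eretic_default, scheme):
    spec, ledger = discrete_sample(30.0, 2.0, seed=13)
    for name in ("mosh", "moah"):
        res = pq.to_mass_fraction(
            pq.quantify(spec, scheme[name], eretic_default), spec.prep
        )
        assert res.mass_fraction == pytest.approx(
            ledger[name]["mass_fraction"], rel=0.005
        )


def test_spiking_linearity_noise_free(eretic_default, scheme):
    levels = [1.0, 2.0, 3.0, 4.0, 5.0, 5.5]
    measured = []
    for i, level in enumerate(levels):
        spec, _ = discrete_sample(11.0 * level, level, seed=40 + i)
        res = pq.to_mass_fraction(
            pq.quantify(spec, scheme["moah"], eretic_default), spec.prep
        )
        measured.append(res.mass_fraction)
    r = np.corrcoef(levels, measured)[0, 1]
    assert r**2 > 0.999
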