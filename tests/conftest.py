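import numpy as np
import pytest

from mohnmr import pulcon_quant as pq
from mohnmr import synth
from mohnmr.model import SamplePrep

# 32k points over 14 ppm keeps the suite fast; acceptance uses the full
# 131072-point default grid.
SMALL_GRID = (-2.0, 12.0, 32768)

PREP = synth.DEFAULT_PREP


@pytest.fixture(scope="session")
def scheme():
    return pq.default_region_scheme()


@pytest.fixture(scope="session")
def quantref_clean():
    """Noise- and artifact-free quantref: the ERETIC factor is exact."""
    recipe = synth.SimulationRecipe(
        components=synth._quantref_components(),
        grid=SMALL_GRID, seed=11, artifacts=None, series_id="clean",
    )
    return synth.simulate_spectrum(recipe)[0]


@pytest.fixture(scope="session")
def eretic_clean(quantref_clean):
    return pq.eretic_from_quantref(quantref_clean)


@pytest.fixture(scope="session")
def quantref_default():
    """Noise-free quantref with solvent artifacts."""
    return synth.simulate_quantref(seed=11, grid=SMALL_GRID)


@pytest.fixture(scope="session")
def eretic_default(quantref_default):
    return pq.eretic_from_quantref(quantref_default)


def discrete_sample(
    mosh_mf: float,
    moah_mf: float,
    seed: int = 0,
    noise_sd: float = 0.0,
    grid=SMALL_GRID,
    prep: SamplePrep = PREP,
    artifacts="default",
):
    """Mineral-oil stand-in from discrete decalin/naphthalene multiplets
    (instead of humps), for linearity/recovery tests."""
    comps = []
    if mosh_mf > 0:
        comps.append(synth.SyntheticComponent(
            name="mosh", mw=138.25,
            concentration=synth.mass_fraction_to_conc(mosh_mf, prep),
            signals=(
                synth.Signal(0.88, 6, "gaussian", 0.004, norm_region="mosh"),
                synth.Signal(1.26, 8, "gaussian", 0.004, norm_region="mosh"),
                synth.Signal(1.70, 4, "gaussian", 0.004, norm_region="mosh"),
            ),
        ))
    if moah_mf > 0:
        comps.append(synth.SyntheticComponent(
            name="moah", mw=128.17,
            concentration=synth.mass_fraction_to_conc(moah_mf, prep),
            signals=(
                synth.Signal(7.84, 4, "gaussian", 0.004, norm_region="moah"),
                synth.Signal(7.46, 4, "gaussian", 0.004, norm_region="moah"),
            ),
        ))
    recipe = synth.SimulationRecipe(
        components=tuple(comps), noise_sd=noise_sd, grid=grid, seed=seed,
        prep=prep,
        artifacts=synth.SolventArtifacts() if artifacts == "default" else artifacts,
        series_id="test", sample_id="discrete",
    )
    return synth.simulate_spectrum(recipe)


@pytest.fixture
def make_discrete_sample():
    return discrete_sample
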