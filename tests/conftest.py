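import numpy as np
import pytest

from gestox import spectra, synth


@pytest.fixture(scope="session")
def plasma_library():
    return synth.build_default_library("plasma")


@pytest.fixture(scope="session")
def urine_library():
    return synth.build_default_library("urine")


@pytest.fixture(scope="session")
def small_plasma_design():
    """Compact plasma cohort design used across tests (fast to render)."""
    return synth.CohortDesign(fluid="plasma", n_per_cell=4, points=4096,
                              noise_sd=0.2, baseline_amplitude=1.0)


@pytest.fixture(scope="session")
def small_plasma_cohort(small_plasma_design):
    """40 rendered plasma spectra with one planted effect, plus truth."""
    effects = synth.EffectSpec((synth.Effect("Citrate", "D20", 0.5),))
    return synth.simulate_cohort(small_plasma_design, effects, seed=11)


@pytest.fixture()
def flat_spectrum():
    """Constant-intensity spectrum covering the plasma region."""
    ppm = np.linspace(9.5, -0.5, 8192)
    meta = spectra.SampleMeta("flat", "C", "D8", "plasma")
    return spectra.Spectrum1D(ppm, np.full(ppm.size, 3.0), meta)


def truth_matrix(effects=(), seed=0, sigma_log=0.15, n_per_cell=8, fluid="plasma"):
    """Metabolite-level FeatureMatrix drawn straight from the truth model."""
    design = synth.CohortDesign(fluid=fluid, n_per_cell=n_per_cell)
    lib = synth.build_default_library(fluid)
    base = synth.default_base_levels(lib)
    spec = synth.EffectSpec(tuple(synth.Effect(*e) for e in effects))
    truth = synth.sample_concentrations(design, spec, base, seed, sigma_log=sigma_log)
    return truth.to_feature_matrix()
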