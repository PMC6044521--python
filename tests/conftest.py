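import numpy as np
import pytest

from chemspec import synthetic as syn
from chemspec.pipeline import spectral_pipeline


@pytest.fixture(scope="session")
def design_full():
    """The 8-condition FT-IR design: 2 pH x 4 dose x 6 bio x 3 tech = 144."""
    return syn.default_design()


@pytest.fixture(scope="session")
def design_gcms():
    """GC-MS design: single technical replicate, 8 pooled-QC injections."""
    return syn.default_design(n_tech=1, n_qc=8)


@pytest.fixture(scope="session")
def spectra_default(design_full):
    return syn.simulate_spectra(syn.SpectraSimConfig(seed=1), design_full)


@pytest.fixture(scope="session")
def pipeline_default(design_full, spectra_default):
    """Full preprocess -> PCA -> PC-DFA -> per-pH CPCA chain on the default
    generator, shared by the geometry tests."""
    return spectral_pipeline(spectra_default, design_full)


@pytest.fixture(scope="session")
def peak_table_default(design_gcms):
    return syn.simulate_peak_table(syn.PeakSimConfig(seed=2), design_gcms)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
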