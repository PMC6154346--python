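import numpy as np
import pytest

from nircal import (MathTreatment, PipelineConfig, default_config,
                    draw_concentrations, run_pipeline, simulate_spectra)
from nircal.synthetic import AnalyteSpec, BandSpec, SyntheticConfig


@pytest.fixture(scope="session")
def rocket_world():
    """Default synthetic study inputs: reference table + spectra (n=156)."""
    cfg = default_config(seed=11, n_samples=156)
    refs = draw_concentrations(cfg)
    spectra = simulate_spectra(refs, cfg)
    return cfg, refs, spectra


@pytest.fixture(scope="session")
def single_band_world():
    """One analyte with a single amide band at 2054 nm over a water matrix."""
    a = AnalyteSpec("A", "umol/g dw", 10.0, 3.0, -50.0, 70.0)
    cfg = SyntheticConfig(
        analytes=[a],
        correlation=np.eye(1),
        bands_per_analyte={"A": [BandSpec(2054, 16, 0.01)]},
        matrix_components={"water": [BandSpec(1920, 40, 0.45)]},
        noise_sd=0.0,
        n_samples=60,
        seed=7,
    )
    refs = draw_concentrations(cfg)
    spectra = simulate_spectra(refs, cfg)
    return cfg, refs, spectra


@pytest.fixture(scope="session")
def default_study():
    """Full default pipeline run (seed fixed); shared across tests."""
    cfg = PipelineConfig(synthetic=default_config(seed=11, n_samples=156))
    return run_pipeline(cfg)
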