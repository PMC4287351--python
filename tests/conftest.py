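import numpy as np
import pytest
from hypothesis import settings

from pol3scan.pwm import build_promoter_model, build_pwm

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from pol3scan.synthetic import SyntheticSpeciesConfig, generate_species


@pytest.fixture(scope="session")
def clean_species():
    """One noise-free synthetic species with both architectures planted."""
    cfg = SyntheticSpeciesConfig(
        species_id="spA", seed=7, n_embedded_loci=3, n_independent_loci=3
    )
    return generate_species(cfg)


@pytest.fixture(scope="session")
def clean_model(clean_species):
    return build_promoter_model(clean_species.training_promoters)


@pytest.fixture
def tata_pwm():
    """Zero-noise TATA PWM from four identical hexamers (pseudocount 0.25)."""
    return build_pwm(["TATAAA"] * 4, pseudocount=0.25)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
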