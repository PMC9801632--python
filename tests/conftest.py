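import numpy as np
import pytest

from axonquant import GroundTruth, SimulationConfig, generate_axon_paths, place_boutons, render_section


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=3)


@pytest.fixture(scope="session")
def bla_section(default_config):
    """One rendered BLA-like section with ground truth (default SNR)."""
    rng = np.random.default_rng(42)
    paths, length = generate_axon_paths(default_config, rng=rng)
    boutons = place_boutons(paths, 0.16, rng)
    truth = GroundTruth(axon_paths=paths, total_axon_length_um=length,
                        bouton_centers_um=boutons, region_label="BLA")
    red, green = render_section(truth, default_config, rng=rng)
    return truth, red, green


@pytest.fixture(scope="session")
def sparse_bouton_section():
    """A section with ~200 boutons placed sparsely along plentiful axon
    (low linear density, so almost no sub-resolution bouton pairs)."""
    cfg = SimulationConfig(seed=3, n_axons=90)
    rng = np.random.default_rng(7)
    paths, length = generate_axon_paths(cfg, rng=rng)
    density = 200.0 / length
    boutons = place_boutons(paths, density, rng)
    truth = GroundTruth(axon_paths=paths, total_axon_length_um=length,
                        bouton_centers_um=boutons, region_label="BLA")
    red, green = render_section(truth, cfg, rng=rng)
    return cfg, truth, red, green
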