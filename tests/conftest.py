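import numpy as np
import pytest

from ernet.phantom import PhantomSpec, generate_network_graph, render_phantom


def noiseless_spec(seed: int = 0, **kw) -> PhantomSpec:
    """Phantom spec with all optical corruption switched off."""
    defaults = dict(seed=seed, peak_photons=None, read_noise=0.0,
                    psf_sigma_px=0.0)
    defaults.update(kw)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def clean_phantom():
    """One noiseless phantom (graph, stack, truth) shared across tests."""
    spec = noiseless_spec(seed=1)
    graph = generate_network_graph(spec)
    stack, truth = render_phantom(graph, spec)
    return spec, graph, stack, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
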