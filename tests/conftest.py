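import numpy as np
import pytest

from patreat.extinction import load_default_extinction
from patreat.fluence import FluenceModel
from patreat.synth import PhantomSpec, TumorSpec, simulate_phantom_scene, simulate_tumor_scene


@pytest.fixture(scope="session")
def ext():
    return load_default_extinction()


@pytest.fixture
def no_attenuation():
    """Fluence model with zero attenuation at every wavelength."""
    return FluenceModel()


@pytest.fixture
def make_phantom(no_attenuation):
    """Factory for small noiseless phantom scenes (no attenuation by default)."""

    def _make(true_sto2=100.0, fluence=None, seed=0, **kwargs):
        kwargs.setdefault("noise_sd", 0.0)
        kwargs.setdefault("pulse_energy_jitter", 0.0)
        kwargs.setdefault("shape", (4, 200, 16))
        spec = PhantomSpec(true_sto2=true_sto2, **kwargs)
        return simulate_phantom_scene(
            spec, fluence if fluence is not None else no_attenuation, seed=seed
        )

    return _make


@pytest.fixture
def make_tumor(no_attenuation):
    """Factory for small noiseless tumor scenes."""

    def _make(seed=0, fluence=None, **kwargs):
        kwargs.setdefault("noise_sd", 0.0)
        kwargs.setdefault("pulse_energy_jitter", 0.0)
        kwargs.setdefault("semi_axes", (2.0, 2.0, 2.0))
        kwargs.setdefault("voxel_spacing", (0.2, 0.2, 0.2))
        spec = TumorSpec(**kwargs)
        return simulate_tumor_scene(
            spec, fluence if fluence is not None else no_attenuation, seed=seed
        )

    return _make
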