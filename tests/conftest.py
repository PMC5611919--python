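import numpy as np
import pytest

import visocm as v
from visocm import phantoms


@pytest.fixture(scope="session")
def quiet_instrument():
    """Noise-free desk-scale instrument (1024 spectral pixels)."""
    return v.InstrumentSpec(n_spectral_pixels=1024, noise=v.NoiseModel(0, 0, 0))


@pytest.fixture(scope="session")
def noisy_instrument():
    """Default-noise desk-scale instrument."""
    return v.InstrumentSpec(n_spectral_pixels=1024)


@pytest.fixture(scope="session")
def reference_spectrum(quiet_instrument):
    """Reference-arm-only spectrum: empty scene, noise off."""
    empty = v.build_phantom(v.PhantomSpec(lateral_shape=(2, 2), layers=()), 100, 2)
    vol = v.simulate_volume(empty, quiet_instrument, seed=0)
    return vol.counts.reshape(-1, quiet_instrument.n_spectral_pixels).mean(axis=0)


@pytest.fixture(scope="session")
def homogeneous_sim(quiet_instrument):
    """Noise-free homogeneous layer (mu = 0.5/mm), regular speckle-free medium."""
    inst = v.InstrumentSpec(n_spectral_pixels=2048, noise=v.NoiseModel(0, 0, 0))
    truth = phantoms.homogeneous_tissue(
        0.5, lateral_shape=(10, 12), backscatter=0.01, regular=True, density_um=2.5
    )
    vol = v.simulate_volume(truth, inst, seed=11)
    tom = v.reconstruct(vol)
    surface = v.detect_surface(tom)
    return {"truth": truth, "instrument": inst, "volume": vol, "tomogram": tom, "surface": surface}


@pytest.fixture(scope="session")
def plaque_sim(noisy_instrument):
    """Congo-red-stained plaque scene with default noise."""
    truth = phantoms.plaque_phantom(lateral_shape=(16, 16), placement_seed=1)
    vol = v.simulate_volume(truth, noisy_instrument, seed=1)
    return {"truth": truth, "volume": vol}
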