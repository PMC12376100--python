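import numpy as np
import pytest

from specmap import synthetic


@pytest.fixture(scope="session")
def harmonic_pes():
    return synthetic.make_harmonic_pes()


@pytest.fixture(scope="session")
def morse_pes():
    return synthetic.make_morse_pes()


@pytest.fixture(scope="session")
def decomposed_pes():
    return synthetic.make_decomposed_pes(seed=3)


@pytest.fixture(scope="session")
def random_frame():
    """A 50-solvent-atom frame with random charges and LJ parameters."""
    return synthetic.make_solvated_frame(n_solvent=50, seed=4)


@pytest.fixture(scope="session")
def cluster_frame():
    """Solvent confined near the probe: no interaction crosses an image."""
    return synthetic.make_solvated_frame(
        n_solvent=40, box=44.0, max_distance=12.0, seed=7
    )


@pytest.fixture(scope="session")
def structured_frames():
    frames, occupied, params = synthetic.make_structured_frames(n_frames=300, seed=11)
    return frames, occupied, params


@pytest.fixture(scope="session")
def ideal_gas_frames():
    return synthetic.make_ideal_gas_frames(n_frames=150, density=0.004, box=30.0, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
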