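import numpy as np
import pytest

from cyclesct import phantom as P
from cyclesct import training as TR


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_spec():
    return P.PhantomSpec()


@pytest.fixture(scope="session")
def default_ct(default_spec):
    return P.render_phase(default_spec, 0)


def micro_config(seed=0, **overrides):
    """Tiny training config for fast unit tests (not the desk preset)."""
    args = dict(crop_size=32, n_patches=16, base_channels=4, disc_channels=4,
                embedding_dim=16, epochs=100, max_iterations=6, seed=seed)
    args.update(overrides)
    return TR.TrainConfig(**args)


@pytest.fixture(scope="session")
def micro_manifest():
    """2 subjects x 10 phases of 32x32 paired slices, in memory."""
    specs = P.make_subject_specs(2, seed=7, grid_size=32, pixel_spacing=8.0)
    return P.generate_paired_dataset(specs, P.DegradationParams(n_angles=16),
                                     output_dir=None)
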