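import numpy as np
import pytest

from spcet.refinement import ScoreModel
from spcet.simulator import SimulationSpec, simulate_tilt_series
from spcet.stack import extract_crops


def build_dataset(**kw):
    defaults = dict(
        n_particles=10,
        betas=np.arange(-60.0, 60.1, 6.0),
        snr=0.5,
        rng_seed=100,
    )
    defaults.update(kw)
    spec = SimulationSpec(**defaults)
    ds = simulate_tilt_series(spec)
    return ds


def build_model(ds, band=(100.0, 6.0), binning=1):
    spec = ds.spec
    stack = extract_crops(
        ds.tilt_images, ds.tilts, ds.particles, spec.box, spec.tomogram_dims, spec.pixel_size
    )
    return ScoreModel(ds.phantom, stack, band=band, tilt_ctfs=ds.tilt_ctfs, binning=binning)


@pytest.fixture(scope="session")
def small_ds():
    """Noisy dataset at the standard SNR, 21 tilts, 10 particles."""
    return build_dataset()


@pytest.fixture(scope="session")
def small_model(small_ds):
    return build_model(small_ds)


@pytest.fixture(scope="session")
def noiseless_ds():
    return build_dataset(n_particles=4, snr=1e9, rng_seed=101, defocus_jitter=0.0)


@pytest.fixture(scope="session")
def noiseless_model(noiseless_ds):
    return build_model(noiseless_ds, band=(100.0, 5.0))
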