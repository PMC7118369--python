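import numpy as np
import pytest

from intravital.synthetic import SimConfig, generate_movie


@pytest.fixture(scope="session")
def default_movie():
    """One default-condition synthetic movie with ground truth."""
    return generate_movie(SimConfig(seed=7))


@pytest.fixture(scope="session")
def noiseless_static_movie():
    """Noiseless, zero-jitter, static-only movie with random-walk drift."""
    cfg = SimConfig(
        seed=11,
        n_static_cells=10,
        n_migratory_cells=0,
        n_cluster_events=0,
        noise_sd=0.0,
        static_jitter_frac=0.0,
        drift_max_step_px=4,
    )
    return cfg, *generate_movie(cfg)


def blob_image(
    shape=(64, 64), center=(32.0, 32.0), sigma=6.0, amplitude=1000.0,
    background=100.0,
):
    """Single bright Gaussian blob on a dark-but-positive background."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    img = background + amplitude * np.exp(
        -((xx - center[0]) ** 2 + (yy - center[1]) ** 2) / (2 * sigma**2)
    )
    return np.rint(img).astype(np.uint16)
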