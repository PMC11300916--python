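import numpy as np
import pytest

from vasculodyn import syndata


def generate_valid_network(n_seeds=10, stroke_px=3, image=(384, 384), start_seed=0):
    """First non-degenerate network from consecutive seeds (the generator
    rejects tessellations too tight to rasterise faithfully)."""
    seed = start_seed
    while True:
        spec = syndata.SyntheticNetworkSpec(
            image_size_px=image, n_seeds=n_seeds, stroke_px=stroke_px, rng_seed=seed)
        try:
            return spec, *syndata.generate_network_image(spec)
        except syndata.DegenerateGeometryError:
            seed += 1


@pytest.fixture(scope="session")
def voronoi_network():
    """One representative generated network with its ground truth."""
    return generate_valid_network(start_seed=1)


@pytest.fixture()
def noisy_table():
    """Three cell lines, three objects, realistic noise."""
    design = syndata.example_design(rng_seed=7)
    return syndata.generate_trajectory_dataset(design), design


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
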