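import numpy as np
import pytest

from speckquant import ImageField, SyntheticSpec, generate_field


@pytest.fixture
def rng():
    return np.random.default_rng(20231101)


@pytest.fixture(scope="session")
def small_field():
    """One 256x256 synthetic field with modest cell density, shared read-only."""
    spec = SyntheticSpec(
        shape=(256, 256),
        n_cells=15,
        speck_fraction=0.4,
        n_extracellular_specks=2,
        seed=7,
    )
    return generate_field(spec, field_id="small")


def make_field(asc, nuclear=None, bit_depth=8, field_id="f"):
    """Wrap float [0,1] rasters into an integer ImageField."""
    lim = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    asc_i = np.round(np.clip(asc, 0, 1) * lim).astype(dtype)
    nuc = nuclear if nuclear is not None else np.zeros_like(asc)
    nuc_i = np.round(np.clip(nuc, 0, 1) * lim).astype(dtype)
    return ImageField(field_id=field_id, nuclear=nuc_i, asc=asc_i, bit_depth=bit_depth)


def gaussian_spot(shape, row, col, sigma, amplitude):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amplitude * np.exp(-((rr - row) ** 2 + (cc - col) ** 2) / (2 * sigma**2))
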