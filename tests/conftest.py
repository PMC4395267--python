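import numpy as np
import pytest

from wpalign import BarcodeSpec, DynamicsSpec, generate_barcode, generate_kymograph


def make_sim(barcode_seed=1, dyn_seed=2, barcode_kwargs=None, dyn_kwargs=None):
    """Seeded default-condition simulation; returns (kymograph, truth, centers)."""
    bspec = BarcodeSpec(seed=barcode_seed, **(barcode_kwargs or {}))
    dyn = DynamicsSpec(seed=dyn_seed, **(dyn_kwargs or {}))
    barcode, centers = generate_barcode(bspec)
    kymo, truth = generate_kymograph(barcode, dyn, band_centers=centers)
    return kymo, truth, centers


@pytest.fixture
def default_sim():
    return make_sim()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
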