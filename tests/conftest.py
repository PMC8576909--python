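import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lungnodule as ln

settings.register_profile(
    "suite", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_phantom():
    """Full-size phantom (48x192x192) with bed and vessels."""
    return ln.generate_phantom(ln.PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def sub_phantom():
    """Small training-scale phantom with a single large nodule."""
    cfg = ln.PhantomConfig(volume_shape=(32, 64, 64), n_nodules=1,
                           diameter_range_mm=(12.0, 25.0), seed=1)
    return ln.generate_phantom(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_roi_dataset(n_per_class, start_seed, diameter_range=(10.0, 22.0)):
    """(windowed 16x48x48 ROI, label) pairs from single-nodule phantoms."""
    data = []
    for malignant, base in ((False, start_seed), (True, start_seed + 1000)):
        cfg = ln.PhantomConfig(volume_shape=(32, 64, 64), n_nodules=1,
                               diameter_range_mm=diameter_range,
                               malignant_fraction=1.0 if malignant else 0.0,
                               seed=0)
        for i in range(n_per_class):
            s = ln.generate_phantom(dataclasses.replace(cfg, seed=base + i))
            roi, _ = ln.crop_roi(s.ct, s.nodule_mask)
            data.append((ln.window_to_grayscale(roi), int(s.per_nodule_malignant[0])))
    return data
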