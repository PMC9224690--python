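import numpy as np
import pytest

from camrad.features.extraction import VolumeWithMasks
from camrad.synthetic import SyntheticSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom_patient() -> VolumeWithMasks:
    """One deterministic phantom patient (4 modalities, nested WT/TC)."""
    spec = SyntheticSpec(n_patients=4, n_positive=2, seed=42)
    return generate_phantom(spec, 0, 1)


@pytest.fixture(scope="session")
def small_volume_mask():
    """A small random volume with an off-centre box mask."""
    rng = np.random.default_rng(7)
    vol = rng.normal(size=(12, 12, 8))
    mask = np.zeros((12, 12, 8), dtype=bool)
    mask[3:9, 2:10, 2:6] = True
    return vol, mask


def tiny_regions(n_cases: int = 12, max_shape=(4, 4, 2), seed: int = 0):
    """Random tiny discretized regions for brute-force oracle comparison."""
    rng = np.random.default_rng(seed)
    cases = []
    for _ in range(n_cases):
        shape = tuple(int(rng.integers(2, s + 1)) for s in max_shape)
        n_bins = int(rng.integers(2, 5))
        levels = rng.integers(1, n_bins + 1, size=shape)
        mask = rng.random(shape) < 0.85
        if not mask.any():
            mask.flat[0] = True
        levels = np.where(mask, levels, 0)
        cases.append((levels, mask, n_bins))
    return cases
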