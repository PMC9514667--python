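import numpy as np
import pytest

from triadspin.model import RateSet, ReducedPairModel
from triadspin.presets import preset_radical
from triadspin.spin import HyperfineTensor, Nucleus, Radical


@pytest.fixture(scope="session")
def free_flavin_model():
    """Free flavin (3 nuclei) + ascorbyl pair, k_X = 1, k_Sigma = 0.1 /us."""
    return ReducedPairModel(
        preset_radical("flavin_3N"),
        preset_radical("ascorbyl_H4"),
        RateSet(k_X=1.0, k_sigma=0.1),
    )


@pytest.fixture(scope="session")
def bound_flavin_model():
    return ReducedPairModel(
        preset_radical("flavin_3N", mobility="bound"),
        preset_radical("ascorbyl_H4"),
        RateSet(k_X=1.0, k_sigma=0.1),
    )


def random_small_model(rng: np.random.Generator) -> ReducedPairModel:
    """A random pair with 0-2 nuclei total (Hilbert dim <= 24)."""

    def make_nucleus(i):
        mult = int(rng.choice([2, 3]))
        a = rng.normal(0.0, 8.0, (3, 3))
        return Nucleus(f"n{i}", mult, HyperfineTensor(0.5 * (a + a.T)))

    n1, n3 = int(rng.integers(0, 2)), int(rng.integers(0, 2))
    r1 = Radical("r1", tuple(make_nucleus(i) for i in range(n1)), mobility="bound")
    r3 = Radical("r3", tuple(make_nucleus(i + 10) for i in range(n3)), mobility="bound")
    rates = RateSet(
        k_X=float(rng.uniform(0.3, 5.0)), k_sigma=float(rng.uniform(0.05, 2.0))
    )
    return ReducedPairModel(r1, r3, rates)
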