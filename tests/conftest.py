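import numpy as np
import pytest

from petseg import PhantomSpec, RegionMask, SUVVolume, generate_phantom


@pytest.fixture(scope="session")
def noiseless_ramp():
    """Single-lesion ramp phantom with blur and noise disabled."""
    return generate_phantom(PhantomSpec(blur_fwhm_mm=0.0, noise_sd_suv=0.0, seed=11))


@pytest.fixture(scope="session")
def noiseless_flat():
    """Single-lesion flat-uptake phantom with blur and noise disabled."""
    return generate_phantom(
        PhantomSpec(
            blur_fwhm_mm=0.0, noise_sd_suv=0.0, lesion_profile="flat", seed=11
        )
    )


@pytest.fixture(scope="session")
def default_phantom():
    """Default-world phantom (blur and noise on)."""
    return generate_phantom(PhantomSpec(seed=5))


def random_fixture(seed: int, shape=(16, 16, 8)):
    """One random SUV volume + masks used by the oracle-equivalence suites."""
    rng = np.random.default_rng(seed)
    suv = SUVVolume(rng.uniform(0.0, 20.0, size=shape), 2.0)
    prostate = rng.random(shape) < 0.5
    if not prostate.any():
        prostate.flat[rng.integers(prostate.size)] = True
    gtv = prostate & (rng.random(shape) < 0.3)
    histo = prostate & (rng.random(shape) < 0.25)
    eval_region = np.zeros(shape, dtype=bool)
    z0 = rng.integers(0, shape[2] - 2)
    eval_region[:, :, z0 : z0 + rng.integers(2, shape[2] - z0 + 1)] = True
    return (
        suv,
        RegionMask(prostate, 2.0, "prostate"),
        RegionMask(gtv, 2.0, "pet_gtv"),
        RegionMask(histo, 2.0, "histo_gtv"),
        RegionMask(eval_region, 2.0, "specimen"),
    )
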