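import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tsallisseg import quantize
from tsallisseg.synthetic_data import LesionSpec, PhantomSpec, generate_phantom

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Seed fixed in advance for every Monte-Carlo style check in the suite.
MC_SEED = 20260928


@pytest.fixture
def rng():
    return np.random.default_rng(MC_SEED)


@pytest.fixture
def noiseless_phantom():
    """Two-value lesion-on-background image plus ground truth."""
    raw, truth = generate_phantom(PhantomSpec(sigma=0.0, seed=0))
    return quantize(raw, 256), truth


def make_phantom(sigma, contrast, seed, morphology="round", noise_model="gaussian"):
    spec = PhantomSpec(
        sigma=sigma,
        seed=seed,
        noise_model=noise_model,
        lesions=[LesionSpec(morphology=morphology, contrast=contrast)],
    )
    raw, truth = generate_phantom(spec)
    return quantize(raw, 256), truth
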