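import numpy as np
import pytest

from em2sas import FixtureSpec, place_points


@pytest.fixture(scope="session")
def rsa_particles():
    """Moderately dense hard-disk configuration with visible structure."""
    spec = FixtureSpec(
        n_particles=300,
        extent=(3000.0, 3000.0),
        mu_r=34.0,
        sigma_r=2.3,
        placement="rsa-hard-disk",
        min_center_distance=60.0,
        seed=42,
    )
    return place_points(spec)


@pytest.fixture(scope="session")
def poisson_particles():
    """Uncorrelated (complete-spatial-randomness) configuration."""
    spec = FixtureSpec(
        n_particles=2000,
        extent=(4000.0, 4000.0),
        mu_r=34.0,
        sigma_r=2.3,
        placement="poisson",
        seed=7,
    )
    return place_points(spec)


@pytest.fixture(scope="session")
def fibril_particles():
    """Parallel-fibril cross-sections: large disks with liquid-like order.

    Mean radius 183 Å with a hard inter-fibril exclusion produces an
    interfibril structure peak near q ≈ 0.013 Å⁻¹ and cylinder
    form-factor features from ≈ 0.02 Å⁻¹ onwards.
    """
    spec = FixtureSpec(
        n_particles=300,
        extent=(12000.0, 12000.0),
        mu_r=183.0,
        sigma_r=15.5,
        placement="rsa-hard-disk",
        min_center_distance=420.0,
        seed=99,
    )
    return place_points(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
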