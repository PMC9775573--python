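import numpy as np
import pytest

import clotherm as ct


@pytest.fixture(scope="session")
def wardrobe():
    return ct.load_wardrobe()


@pytest.fixture(scope="session")
def geometry():
    return ct.default_geometry()


@pytest.fixture
def dry_env():
    """Cool-chamber conditions used for heavy protective combinations."""
    return ct.Environment(air_temperature=10.0, relative_humidity=40.0, air_velocity=0.18)


@pytest.fixture
def mild_env():
    """Chamber conditions used for individual items and light combinations."""
    return ct.Environment(air_temperature=20.0, relative_humidity=40.0, air_velocity=0.18)


@pytest.fixture
def wet_env():
    """Isothermal sweating-skin conditions (air at the surface set-point)."""
    return ct.Environment(air_temperature=34.0, relative_humidity=40.0, air_velocity=0.40)


@pytest.fixture
def dry_spec(mild_env):
    return ct.SyntheticSpec(
        mode="dry", environment=mild_env, true_zone_insulation=0.35, duration=1800.0, seed=7
    )


@pytest.fixture
def wet_spec(wet_env):
    return ct.SyntheticSpec(
        mode="wet", environment=wet_env, true_zone_evap_resistance=18.7, duration=1800.0, seed=7
    )


@pytest.fixture
def heterogeneous_insulation(geometry):
    """Zone insulations spanning 0.1-0.9 m2K/W, far from uniform."""
    rng = np.random.default_rng(42)
    return {z: float(v) for z, v in zip(geometry.zone_ids, rng.uniform(0.1, 0.9, 17))}
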