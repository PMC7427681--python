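import numpy as np
import pytest

from sirtdose.phantom import PhantomSpec, TumorSpec, build_phantom


def small_spec(**overrides) -> PhantomSpec:
    """A reduced digital-liver phantom used across tests (fast to build)."""
    kwargs = dict(
        seed=0,
        liver_semiaxes_mm=(45.0, 35.0, 30.0),
        lpt_plane_x_mm=5.0,
        margin_mm=20.0,
        fine_spacing_mm=2.0,
        tumors=(
            TumorSpec(center_mm=(-18.0, 5.0, 3.0), radius_mm=12.0, tnr=4.0),
            TumorSpec(center_mm=(20.0, -8.0, -5.0), radius_mm=11.0, tnr=4.0),
        ),
        administered_gbq=(0.9, 0.6),
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def base_spec():
    return small_spec()


@pytest.fixture(scope="session")
def base_phantom(base_spec):
    return build_phantom(base_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
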