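import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def torus_phantom():
    from tomopipe.simulator import make_phantom
    return make_phantom("torus", 24, {"ring_radius": 6, "tube_radius": 3})


@pytest.fixture(scope="session")
def blob_phantom():
    from tomopipe.simulator import make_phantom
    return make_phantom("asymmetric-blob", 32, {"seed": 3})


@pytest.fixture(scope="session")
def small_tilt_fixture():
    """Noise-free tilt series of a few particles: shared by reconstruction and
    extraction equivalence tests."""
    from tomopipe.simulator import (make_phantom, place_particles,
                                    render_specimen, simulate_tilt_series,
                                    TiltScheme)
    phantom = make_phantom("torus", 24, {"ring_radius": 6, "tube_radius": 3})
    truth = place_particles((96, 96, 48), 4, min_dist=24, border=14, seed=7)
    specimen = render_specimen(truth, phantom, (96, 96, 48))
    series = simulate_tilt_series(specimen, TiltScheme(-45, 45, 3), seed=7)
    return {"phantom": phantom, "truth": truth, "specimen": specimen,
            "series": series}
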