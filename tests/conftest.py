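import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_helix_track():
    """Ideal circular helix: no rotational/translational diffusion, no
    noise, no reversals."""
    from halotaxis import GeneratorConfig, generate_swimmer_track

    cfg = GeneratorConfig(
        swim_speed=2.0,
        mean_run_duration=1e9,
        rotational_diffusivity=0.0,
        translational_diffusivity=0.0,
        helix_pitch_angle=0.3,
        helix_angular_frequency=3.0,
        noise_lateral=0.0,
        noise_axial=0.0,
        duration=60.0,
        seed=1,
    )
    return generate_swimmer_track(cfg)


@pytest.fixture(scope="session")
def noisy_population():
    """Small population at the reference study conditions (1.9 um/s,
    tau_run 14.7 s, localisation noise on)."""
    from halotaxis import GeneratorConfig, generate_population

    cfg = GeneratorConfig(duration=60.0, seed=5)
    return generate_population(cfg, 12, seed=42)
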