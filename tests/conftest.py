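import pytest

from divebottom3d.pipeline_io import PipelineParams, run_pipeline
from divebottom3d.synthetic_data import SimConfig, simulate_deployment


@pytest.fixture(scope="session")
def default_deployment():
    """A realistic noisy deployment: 8 dives, continuous acoustics."""
    cfg = SimConfig(seed=101, n_dives=8, duty_cycle=12.0, drift_dive_fraction=0.0)
    frame, fixes, truth = simulate_deployment(cfg)
    return cfg, frame, fixes, truth


@pytest.fixture(scope="session")
def noisefree_deployment():
    """Noise-free sensors, no current, ~20-minute dives."""
    cfg = SimConfig(
        seed=11, n_dives=5, duty_cycle=12.0, drift_dive_fraction=0.0,
        prey_intensity=0.0, accel_noise_sd=0.0, mag_noise_sd=0.0,
        noise_level_sd=0.0, depth_offset=0.0, depth_drift_per_hour=0.0,
        bottom_duration_mean=700.0,
    )
    frame, fixes, truth = simulate_deployment(cfg)
    return cfg, frame, fixes, truth


@pytest.fixture(scope="session")
def pipeline_result(default_deployment):
    cfg, frame, fixes, truth = default_deployment
    return run_pipeline(
        frame, fixes, PipelineParams(radii=(1.5,), mc_samples=30_000, seed=9)
    )


@pytest.fixture(scope="session")
def noisefree_pipeline(noisefree_deployment):
    cfg, frame, fixes, truth = noisefree_deployment
    return run_pipeline(
        frame, fixes, PipelineParams(radii=(1.5,), mc_samples=20_000, seed=4)
    )
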