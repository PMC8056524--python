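import pytest

from amytrial.cohort import CohortConfig, generate_cohort, simulate_measurements
from amytrial.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def default_bundle():
    """Full pipeline result on the default 237-subject cohort (package
    defaults, seed 0)."""
    return run_pipeline(PipelineConfig())


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-subject cohort for cheaper structural checks."""
    cfg = CohortConfig(n_subjects=60, seed=7)
    profiles, trajectories, scan_times = generate_cohort(cfg)
    return cfg, profiles, trajectories, scan_times


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Noise-free measurements: observed values are exact model values."""
    cfg = CohortConfig(n_subjects=40, seed=3, noise_scale=0.0)
    profiles, trajectories, scan_times = generate_cohort(cfg)
    measurements = simulate_measurements(trajectories, scan_times, cfg)
    return cfg, profiles, trajectories, scan_times, measurements
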