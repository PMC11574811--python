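import numpy as np
import pytest

from eegmarkers.pipeline import RunConfig, run_pipeline
from eegmarkers.recording import PreprocConfig
from eegmarkers.simulate import PHENOTYPES, simulate_subject


@pytest.fixture(scope="session")
def control_recording():
    """One healthy-control recording (alpha peak at 10 Hz, short timescale)."""
    rec, _ = simulate_subject(PHENOTYPES["control"], seed=42)
    return rec


@pytest.fixture(scope="session")
def flat_recording():
    """One peakless long-timescale recording."""
    rec, _ = simulate_subject(PHENOTYPES["doc_flat"], seed=43)
    return rec


@pytest.fixture(scope="session")
def small_pipeline_config(tmp_path_factory):
    """Down-scaled cohort (60-s recordings, 14 subjects) for plumbing tests."""
    out = tmp_path_factory.mktemp("pipe")
    return RunConfig(
        n_control=4, n_mcs=5, n_uws=5, seed=11, n_boot=500,
        preproc=PreprocConfig(clip_s=60.0), acw_max_lag_s=10.0,
        out_dir=str(out / "run"),
    )


def _small_cohort(config):
    from eegmarkers.simulate import simulate_cohort

    return simulate_cohort(config.n_control, config.n_mcs, config.n_uws,
                           config.paths, config.noise_sd, config.seed,
                           duration_s=60.0)


@pytest.fixture(scope="session")
def small_cohort(small_pipeline_config):
    return _small_cohort(small_pipeline_config)


@pytest.fixture(scope="session")
def default_cohort_run(tmp_path_factory):
    """Full paper-shaped cohort (25 controls, 47 MCS, 48 UWS) through the
    complete pipeline.  Shared across the acceptance tests; one run takes
    under a minute."""
    out = tmp_path_factory.mktemp("cohort")
    cfg = RunConfig(seed=0, out_dir=str(out / "run"), n_boot=5000)
    return run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
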