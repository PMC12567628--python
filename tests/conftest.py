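import warnings

import numpy as np
import pytest

from respemg import PipelineConfig, SynthSpec, run_pipeline, simulate_semg

# the Nyquist-margin warning of the under preset is expected and assessed
# explicitly in test_filtering
warnings.filterwarnings("ignore",
                        message=".*margin to the Nyquist limit.*")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_recording():
    """One default synthetic recording (60 s, rr=12, hr=80, SNR 5)."""
    spec = SynthSpec(seed=7)
    group, truth = simulate_semg(spec)
    return group, truth


@pytest.fixture(scope="session")
def default_pipeline_result(default_recording):
    group, _ = default_recording
    return run_pipeline(group, PipelineConfig.preset_config("default"))


@pytest.fixture(scope="session")
def preset_sweep():
    """Per-preset feature tables over 8 seeded recordings (shared by the
    slower direction/recovery tests)."""
    tables = {p: [] for p in ("default", "under", "over")}
    truths = []
    for seed in range(8):
        group, truth = simulate_semg(SynthSpec(seed=seed))
        truths.append(truth)
        for p in tables:
            res = run_pipeline(group, PipelineConfig.preset_config(p))
            tables[p].append(res.peakset.to_frame())
    return tables, truths
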