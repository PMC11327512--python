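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
def tone_2s_32k() -> np.ndarray:
    """2-s 440-Hz sine at 32 kHz, peak 0.8."""
    t = np.arange(64_000) / 32_000
    return 0.8 * np.sin(2 * np.pi * 440.0 * t)


@pytest.fixture(scope="session")
def tiny_store(tmp_path_factory):
    """Small 4-fold synthetic store for dataset/training unit tests.

    8 subjects (2 per group x sex cell), 2-s recordings generated directly
    at the 32 kHz analysis rate, one pre/post pair per subject.
    """
    from swallownet.dataset import build_store_from_recordings
    from swallownet.synth import (
        PostDelta,
        SynthConfig,
        generate_cohort_recordings,
        twin_key,
    )

    cfg = SynthConfig(
        n_per_cell=2,
        duration_s=2.0,
        sample_rate=32_000,
        post_delta=PostDelta(2.0, 6.0, 10.0),
        seed=7,
    )
    recs = generate_cohort_recordings(cfg)
    path = tmp_path_factory.mktemp("store") / "tiny.h5"
    plan, pairs = build_store_from_recordings(
        recs, path, k=4, seed=7, match_key=twin_key
    )
    return {"path": path, "plan": plan, "pairs": pairs, "recordings": recs}
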