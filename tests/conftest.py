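"""Shared fixtures: the default-conditions synthetic study, run once per session."""

from __future__ import annotations

import pytest

from emgtorque import PipelineConfig, SynthConfig, gen_session_set
from emgtorque.pipeline import run_pipeline


@pytest.fixture(scope="session")
def study_session_set():
    """The full synthetic study: 12 angles x 2 sessions at default noise."""
    return gen_session_set(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def study_result(study_session_set):
    """End-to-end pipeline result (with preprocessing) on the default study."""
    return run_pipeline(study_session_set, PipelineConfig(), seed=7)


@pytest.fixture(scope="session")
def study_result_no_preprocess(study_session_set):
    """Same study and seed, but features computed on the raw signals."""
    return run_pipeline(
        study_session_set, PipelineConfig(preprocess_enabled=False), seed=7
    )


@pytest.fixture(scope="session")
def small_session_set():
    """A reduced study (4 angles, short trials) for fast end-to-end checks."""
    cfg = SynthConfig(duration_s=6.0, seed=11)
    return gen_session_set(cfg, angles=(60.0, 70.0, 80.0, 90.0), sessions_per_angle=2)


@pytest.fixture(scope="session")
def small_pipeline_config():
    from emgtorque import BinSpec, TrainConfig

    return PipelineConfig(
        bin_spec=BinSpec(centers=(60.0, 70.0, 80.0, 90.0)),
        train=TrainConfig(max_epochs=300),
    )
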