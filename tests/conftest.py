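"""Shared fixtures.

The expensive artifacts (trained pipeline runs) are session-scoped and
shared between the unit suite and the acceptance tests so the whole run
stays inside a desk-scale time budget.
"""

from __future__ import annotations

import pytest

from segfuse.net_stage import NetConfig
from segfuse.phantom import PhantomConfig, generate_subject
from segfuse.pipeline import PipelineConfig, SplitConfig, run_pipeline


@pytest.fixture(scope="session")
def phantom_config():
    return PhantomConfig(n_subjects=8, seed=11)


@pytest.fixture(scope="session")
def phantom_subjects(phantom_config):
    """Six default phantoms, generated once."""
    return [generate_subject(phantom_config, i) for i in range(6)]


def fast_pipeline_config(out_dir, cohort_seed=7, **overrides) -> PipelineConfig:
    """Desk-scale pipeline config used across tests (depth-2, width-8 nets)."""
    defaults = dict(
        out_dir=str(out_dir),
        phantom=PhantomConfig(n_subjects=8, seed=cohort_seed),
        split=SplitConfig(fraction=0.75, seed=cohort_seed),
        binary_net=NetConfig(
            in_channels=1,
            n_classes=2,
            epochs=25,
            batch_size=6,
            learning_rate=2e-2,
            class_weights="inverse",
            seed=1,
        ),
        multiclass_net=NetConfig(
            in_channels=3,
            n_classes=4,
            epochs=40,
            batch_size=6,
            learning_rate=2e-2,
            class_weights="inverse",
            seed=2,
        ),
    )
    defaults.update(overrides)
    return PipelineConfig(**defaults)


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """Two identical full pipeline runs on a seeded 8-subject cohort.

    Returns (config_a, report_a, artifacts_a, config_b, report_b) where the
    second run only serves the bit-reproducibility check.
    """
    base = tmp_path_factory.mktemp("pipeline")
    cfg_a = fast_pipeline_config(base / "run_a")
    report_a, artifacts_a = run_pipeline(cfg_a, return_artifacts=True)
    cfg_b = fast_pipeline_config(base / "run_b")
    report_b = run_pipeline(cfg_b)
    return cfg_a, report_a, artifacts_a, cfg_b, report_b
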