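"""Shared fixtures: generated slides and trained models reused across tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import slidemil as sm
from slidemil.config import RunConfig
from slidemil import pipeline

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def positive_slide():
    """One deterministic synthetic slide with two tumour foci + its masks."""
    spec = sm.SyntheticSlideSpec(
        tumour_present=True, tumour_focus_diameters_um=(100.0, 250.0), seed=3
    )
    slide, tumour, tissue = sm.generate_slide(spec)
    return slide, tumour, tissue


@pytest.fixture(scope="session")
def bag_study():
    """Trained ABMIL on the default synthetic feature-bag cohort.

    Conditions: effect size 2, witness count 3, 100 training / 40
    validation / 40 test bags, fixed seeds.
    """
    tr_bags, tr_y = sm.generate_feature_bags(sm.BagSimSpec(n_bags_per_class=50, seed=10))
    va_bags, va_y = sm.generate_feature_bags(sm.BagSimSpec(n_bags_per_class=20, seed=11))
    te_bags, te_y = sm.generate_feature_bags(sm.BagSimSpec(n_bags_per_class=20, seed=12))
    params = sm.init_params(32, seed=1)
    fitted, history = sm.train(
        params, tr_bags, tr_y, sm.TrainConfig(seed=2), va_bags, va_y
    )
    return {
        "model": fitted,
        "history": history,
        "test_bags": te_bags,
        "test_labels": te_y,
    }


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full synthetic end-to-end run (default demo configuration)."""
    out = tmp_path_factory.mktemp("demo")
    cfg = RunConfig(seed=1, out_dir=str(out))
    summary = pipeline.demo(cfg)
    return cfg, summary
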