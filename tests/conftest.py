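"""Shared fixtures: small synthetic sessions and a full-size study.

Everything is generated programmatically at test time with fixed seeds;
the expensive cohort (16 participants x 8 conditions x 5 min) is built
once per session and shared by the acceptance-level tests.
"""

import numpy as np
import pytest
from hypothesis import settings

import triadtalk as tt
from triadtalk import pipeline, vad

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_params():
    return vad.VadParams()


@pytest.fixture(scope="session")
def small_bundle():
    """One participant, short conditions — cheap end-to-end material."""
    cfg = tt.GeneratorConfig(duration_s=60.0)
    return cfg, tt.generate_session(cfg, "P01", 20240001)


@pytest.fixture(scope="session")
def full_study():
    """Full study cohort at the nominal design size, with ground truth."""
    cfg = tt.GeneratorConfig()  # 16 participants, 300 s conditions
    bundles = tt.generate_study(cfg, 20240002)
    return cfg, bundles


@pytest.fixture(scope="session")
def full_study_measures(full_study):
    cfg, bundles = full_study
    table, ratings = pipeline.study_measures([b.session for b in bundles])
    return cfg, bundles, table, ratings
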