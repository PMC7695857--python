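import numpy as np
import pytest

import helixbreak as hb
from helixbreak.chemistry import ChemConfig
from helixbreak.pipeline import PipelineConfig


@pytest.fixture(scope="session")
def small_segment():
    """500 bp helix with histones every 100 bp."""
    seg = hb.build_helix_segment(500, seed=11)
    return hb.place_histones(seg, 100)


@pytest.fixture(scope="session")
def bare_segment():
    """200 bp helix without histones."""
    return hb.build_helix_segment(200, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def fast_pipeline_config(**overrides) -> PipelineConfig:
    """Desk-scale run small enough for paired-replicate tests.

    kGy-scale doses compensate for the tiny water mass of a fitted
    desk-scale container (yields are reported per Gy per Gbp and the
    deposition process is dose-linear, so this only buys statistics).
    """
    defaults = dict(n_bp=5000, dose_gy=3000.0,
                    chem=ChemConfig(dt_ns=0.002))
    defaults.update(overrides)
    return PipelineConfig(**defaults)
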