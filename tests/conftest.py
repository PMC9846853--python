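import numpy as np
import pytest

import voicerep as vr


@pytest.fixture(scope="session")
def stim48():
    """Balanced catalog: 12 stimuli per subcategory, 48 total."""
    return vr.generate_stimulus_set(12, seed=0)


@pytest.fixture(scope="session")
def clean_pattern(stim48):
    """Strong vocal pattern, tiny noise: linearly separable by construction."""
    cfg = vr.GenerativeConfig(vocal_effect=2.0, noise_sd=0.05, seed=1)
    return vr.generate_beta_patterns(stim48, cfg)


@pytest.fixture(scope="session")
def noise_pattern(stim48):
    """No categorical structure at all (control-ROI-like)."""
    cfg = vr.GenerativeConfig(vocal_effect=0.0, speech_gain=0.0, seed=2)
    return vr.generate_beta_patterns(stim48, cfg)


@pytest.fixture(scope="session")
def prob_bump():
    """Single broad probability bump centered mid-grid."""
    return vr.generate_volume_maps(
        (24, 24, 24), [(12, 12, 12)], [1.0], kind="probability", seed=5
    )


@pytest.fixture(scope="session")
def three_bump_tmap():
    """Three well-separated t-statistic bumps along x."""
    return vr.generate_volume_maps(
        (40, 24, 24),
        [(8, 12, 12), (20, 12, 12), (32, 12, 12)],
        [8.0, 9.0, 7.0],
        kind="tstat",
        seed=6,
    )
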