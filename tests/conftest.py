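import numpy as np
import pytest

from vivorate import respirometry as rp
from vivorate import synthetic_video as sv


@pytest.fixture(scope="session")
def standard_scenario():
    """A realistic 20-s clip: 191 bpm, mild jitter and sensor noise."""
    return sv.BreathingScenario(rate_bpm=191.0, jitter_cv=0.05, noise_sd=0.02, seed=3)


@pytest.fixture(scope="session")
def standard_clip(standard_scenario):
    return sv.render_breathing_clip(standard_scenario)


@pytest.fixture(scope="session")
def clean_scenario():
    """Noiseless 10-s clip for displacement-accuracy oracles."""
    return sv.BreathingScenario(
        rate_bpm=191.0, jitter_cv=0.05, noise_sd=0.0, duration_s=10.0, seed=11
    )


@pytest.fixture(scope="session")
def clean_clip(clean_scenario):
    return sv.render_breathing_clip(clean_scenario)


@pytest.fixture(scope="session")
def clean_tracks(clean_clip, clean_scenario):
    seq, _ = clean_clip
    seeds = rp.detect_features(seq, [rp.RoiContour(sv.flank_roi(clean_scenario))])
    return rp.track_features(seq, seeds)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
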