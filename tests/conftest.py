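import numpy as np
import pytest

from hrvidh import BeatSeries, ModulationProfile, generate_tachogram


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def constant_series():
    """240-minute constant tachogram at 1000 ms (HR 60)."""
    profile = ModulationProfile(
        base_rr=1000.0, amp_vlf=0.0, amp_lf=0.0, amp_hf=0.0, noise_sd=0.0
    )
    return generate_tachogram(profile, duration=14400.0, seed=0)


@pytest.fixture
def noisy_series():
    """240-minute tachogram with mild broadband variability."""
    profile = ModulationProfile(base_rr=900.0, noise_sd=15.0)
    return generate_tachogram(profile, duration=14400.0, seed=42)


def make_series(rr_ms):
    """BeatSeries with the given RR values, times from their cumulative sum."""
    rr = np.asarray(rr_ms, dtype=float)
    return BeatSeries(np.cumsum(rr) / 1000.0, rr)


@pytest.fixture
def series_factory():
    return make_series
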