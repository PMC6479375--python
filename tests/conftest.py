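import numpy as np
import pytest

from delda import SynthConfig, decompose, effect_presets, generate
from delda.entropy import build_de_table


def small_config(preset: str, seed: int, **overrides) -> SynthConfig:
    """Desk-sized generator config: 18 trials, 8 channels, 3-s clips."""
    kwargs = dict(
        seed=seed,
        n_subjects=3,
        n_clips_per_class=2,
        n_sessions=1,
        n_channels=8,
        clip_seconds=3.0,
        effect=effect_presets()[preset],
    )
    kwargs.update(overrides)
    return SynthConfig(**kwargs)


@pytest.fixture(scope="session")
def strong_small():
    """(TrialSet, ground truth) with a strong class effect, 18 trials."""
    return generate(small_config("strong", seed=11))


@pytest.fixture(scope="session")
def strong_small_bands(strong_small):
    trial_set, _ = strong_small
    return decompose(trial_set)


@pytest.fixture(scope="session")
def strong_small_de(strong_small_bands):
    per_band, combined = build_de_table(strong_small_bands)
    return per_band, combined


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
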