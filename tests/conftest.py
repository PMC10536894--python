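import pytest

from eegfusion.model import BranchSpec, FusionModelSpec
from eegfusion.preprocessing import eegmmidb_recipe
from eegfusion.synth import SynthConfig, generate_recording


@pytest.fixture(scope="session")
def small_recording():
    """8-channel, 12-trial recording with a clear class-linked rhythm."""
    cfg = SynthConfig(
        n_channels=8, n_trials=12, erd_depth=0.8, noise_std=0.5,
        inter_trial_gap_s=1.0, seed=42,
    )
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def small_windows(small_recording):
    """Windowed dataset from the standard 160 Hz recipe (96 windows)."""
    return eegmmidb_recipe(small_recording)


@pytest.fixture()
def tiny_spec():
    """One small branch; cheap enough for optimization tests."""
    return FusionModelSpec(
        branches=(
            BranchSpec(
                n_temporal_filters=4, temporal_kernel_len=16,
                n_separable_filters=8, separable_kernel_len=8,
                depth_multiplier=2, pool1_len=4, pool2_len=8, dropout_p=0.25,
            ),
        ),
        n_channels=8, window_len=80, n_classes=2,
    )
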