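import numpy as np
import pytest

import nystagrid as ng


@pytest.fixture(scope="session")
def horizontal_clip():
    """Rendered clip with a +30 px/s horizontal slow phase, 1 Hz beat."""
    spec = ng.SynthVideoSpec(
        slow_phase_velocity=(30.0, 0.0, 0.0), beat_frequency=1.0, duration=2.0, seed=11
    )
    frames, truth, ttruth = ng.render_eye_video(spec)
    return spec, frames, truth, ttruth


@pytest.fixture(scope="session")
def horizontal_tracking(horizontal_clip):
    _, frames, _, _ = horizontal_clip
    trace, fits = ng.track_clip(frames)
    return trace, fits


@pytest.fixture(scope="session")
def rotation_clip():
    """Rendered clip rotating at a constant +15 deg/s (0.5 deg/frame)."""
    spec = ng.SynthVideoSpec(
        slow_phase_velocity=(0.0, 0.0, 15.0), beat_frequency=0.0, duration=1.0, seed=12
    )
    frames, truth, ttruth = ng.render_eye_video(spec)
    return spec, frames, truth, ttruth


@pytest.fixture(scope="session")
def synthetic_datasets():
    """Small class-balanced grid datasets from the default templates."""
    return ng.generate_dataset(150, 60, seed=7)


@pytest.fixture(scope="session")
def trained_model(synthetic_datasets):
    train_ds, val_ds = synthetic_datasets
    cfg = ng.NetworkConfig(conv_depth=2, base_neurons=16, max_epochs=20, seed=7)
    model = ng.build_network(cfg)
    history = ng.train(model, train_ds, val_ds)
    return model, history
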