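import numpy as np
import pytest

from eegfuse import (
    ConvNetSpec,
    SyntheticSpec,
    average_presentations,
    extract_convnet_features,
    generate_epochs,
    init_filters,
)


def null_templates(n_classes, channels=(0,)):
    """Evoked templates with zero amplitude: exchangeable classes."""
    return [
        {"amplitude": 0.0, "latency": 0.2, "width": 0.05, "channels": list(channels)}
        for _ in range(n_classes)
    ]


@pytest.fixture(scope="session")
def small_epochs():
    """2 classes x 10 images x 2 presentations, 4 channels — separable."""
    spec = SyntheticSpec(
        n_classes=2,
        images_per_class=10,
        n_channels=4,
        noise_sd=2.0,
        seed=42,
    )
    return generate_epochs(spec)


@pytest.fixture(scope="session")
def small_averaged(small_epochs):
    return average_presentations(small_epochs)


@pytest.fixture(scope="session")
def tiny_convnet():
    """Small filter bank compatible with 250-sample rows."""
    return init_filters(ConvNetSpec(n_maps=5, filter_len=30, pool_width=10, seed=3))


@pytest.fixture(scope="session")
def small_features(small_averaged, tiny_convnet):
    return extract_convnet_features(small_averaged, tiny_convnet)
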