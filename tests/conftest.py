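import numpy as np
import pytest

from enosedx.preprocess import BreathprintImage, traces_to_images
from enosedx.synthetic import (default_class_model, default_site_model,
                               simulate_cohort)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Eight S1 traces (3 cancer, 2 healthy, 3 diseased), seeded."""
    return simulate_cohort(
        3, 2, 3, "S1",
        class_model=default_class_model(),
        site_model=default_site_model("S1"),
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_images(tiny_cohort):
    return traces_to_images(tiny_cohort, scheme="per_channel_zscore")


@pytest.fixture
def impulse_image():
    """One-hot breathprint: a unit spike at flattened position 33 (row 2, col 1)."""
    tensor = np.zeros((14, 16, 16))
    tensor[:, 2, 1] = 1.0
    return BreathprintImage(sample_id="impulse", tensor=tensor, label="healthy_control")


def make_separable_images(n_per_class=10, seed=0):
    """Trivially separable toy images: class mean +/-1 plus small noise."""
    rng = np.random.default_rng(seed)
    images = []
    for i in range(2 * n_per_class):
        cls = i % 2
        tensor = (1.0 if cls else -1.0) + 0.05 * rng.standard_normal((14, 16, 16))
        images.append(
            BreathprintImage(
                sample_id=f"toy-{i:03d}",
                tensor=tensor,
                label="lung_cancer" if cls else "healthy_control",
            )
        )
    return images
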