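import numpy as np
import pytest

from cavigap.synthetic import CONDITIONS, MonolayerSpec, generate_monolayer, insert_gaps


@pytest.fixture(scope="session")
def small_spec() -> MonolayerSpec:
    """A 512-px channel field, small enough for fast per-test generation."""
    return MonolayerSpec(field_width_px=512, field_height_px=512, n_cells=40, seed=42)


@pytest.fixture(scope="session")
def small_field(small_spec):
    """(image, label_map) of the small channel, generated once per session."""
    return generate_monolayer(small_spec)


@pytest.fixture(scope="session")
def gapped_field(small_spec, small_field):
    """Small channel with control-condition gaps and its truth table."""
    image, label_map = small_field
    img, truth = insert_gaps(
        image, label_map, CONDITIONS["CTRL"], seed=small_spec.seed,
        pixel_size_um=small_spec.pixel_size_um, intensity_gap=small_spec.intensity_gap,
    )
    return img, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
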