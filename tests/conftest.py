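import numpy as np
import pytest

from mucinquant.filter_hsv import FilterHSVConfig
from mucinquant.smart_seg import fit_color_classes, seeds_from_truth
from mucinquant.synthetic_data import FieldSpec, generate_field


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pas_config():
    return FilterHSVConfig.for_stain("pas")


@pytest.fixture(scope="session")
def ab_config():
    return FilterHSVConfig.for_stain("ab")


@pytest.fixture(scope="session")
def pas_field():
    """Default-noise PAS field at 20% true area fraction."""
    return generate_field(FieldSpec(stain="pas", target_area_fraction=0.20, seed=42))


@pytest.fixture(scope="session")
def pas_model(pas_field):
    seeds = seeds_from_truth(pas_field.image, pas_field.labels, rng=np.random.default_rng(7))
    return fit_color_classes(seeds)
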