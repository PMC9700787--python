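import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from enviroscore.impact_model import CATEGORY_CODES, ImpactVector
from enviroscore.normalization import bundled_efsi_tables
from enviroscore.synthetic_data import GeneratorConfig, generate_basket, reference_item


@pytest.fixture(scope="session")
def efsi_tables():
    return bundled_efsi_tables()


@pytest.fixture
def sugar_like():
    """Calibrated grade-A fixture: EFSI exactly 3.79e-4."""
    return reference_item(3.79e-4, item_id="sugar_like", product="Sugar")


@pytest.fixture
def basket():
    return generate_basket(GeneratorConfig(seed=7))


@pytest.fixture
def unit_vector():
    """Impact vector numerically equal to the bundled NF in every category."""
    nf, _ = bundled_efsi_tables()
    return ImpactVector({c: nf[c] for c in CATEGORY_CODES})
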