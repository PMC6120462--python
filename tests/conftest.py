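import pytest

from iredmine.align import ScoringParams
from iredmine.simulate import FamilyConfig, generate_family, plant_negatives


@pytest.fixture(scope="session")
def params() -> ScoringParams:
    return ScoringParams()


@pytest.fixture(scope="session")
def family():
    """20 positives (10 per donor clade) plus one negative per mode."""
    fam = generate_family(FamilyConfig(n_taxa=20, seed=11))
    return plant_negatives(fam, per_mode=1)


@pytest.fixture(scope="session")
def positives_only():
    return generate_family(FamilyConfig(n_taxa=12, seed=7))
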