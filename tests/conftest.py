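import numpy as np
import pytest

from glycoqc.model import Conditions, VARIANTS, assemble_rates


@pytest.fixture
def phys_conditions():
    """Low production, fast folding, trace misfolding, moderate background."""
    return Conditions(kpt=0.1, mf=0.001, kf=1.0, Pb=1.0)


@pytest.fixture
def phys_rates(phys_conditions):
    return assemble_rates(
        VARIANTS["PHYS"], phys_conditions,
        {"kc": 100.0, "kg": 10.0, "kmg": 0.01, "kd": 0.1},
    )


def all_variant_fixtures(seed: int, n_per_variant: int):
    """Seeded random rate sets across every pathway architecture."""
    from glycoqc.io import random_rate_fixture

    out = []
    for i, variant in enumerate(VARIANTS.values()):
        out.extend(random_rate_fixture(variant, seed + i, n_per_variant))
    return out
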