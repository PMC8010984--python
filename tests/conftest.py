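import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from sine_scout.synthetic_data import (
    FamilySpec,
    SimulationConfig,
    generate_genome_with_families,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_dataset():
    """One-family 300-kb genome with partner LINE and HTT event."""
    cfg = SimulationConfig(
        genome_bp=300_000,
        n_genes=12,
        families=[FamilySpec(name="SE1", n_copies=30)],
        partner_line=True,
        htt_event=True,
        seed=3,
    )
    return generate_genome_with_families(cfg)


@pytest.fixture(scope="session")
def spaced_dataset():
    """Widely spaced implants so every copy has clean 500-bp flanks."""
    cfg = SimulationConfig(
        genome_bp=900_000,
        n_genes=30,
        families=[FamilySpec(name="SE1", n_copies=100)],
        min_implant_spacing=1300,
        seed=11,
    )
    return generate_genome_with_families(cfg)
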