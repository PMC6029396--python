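import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from bivdom import GenomeLayout, MarkConfig, SimulationConfig, plant_loci


@pytest.fixture
def layout():
    return GenomeLayout({"chrT": 1_000_000})


@pytest.fixture
def rng():
    return np.random.default_rng(20230)


@pytest.fixture
def two_mark_manifest():
    """Small two-mark experiment with a 30/40/30 co-occupancy design."""
    config = SimulationConfig(
        seed=11, genome={"chrS": 5_000_000}, n_loci=120,
        locus_length_range=(1500, 2500),
        marks={"A": MarkConfig(0.0025, 8.0), "B": MarkConfig(0.0025, 8.0)},
        cooccupancy_design={frozenset("AB"): 0.30, frozenset("A"): 0.40,
                            frozenset("B"): 0.30},
    )
    return plant_loci(config)
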