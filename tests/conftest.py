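import numpy as np
import pytest

from telocus import build_compartments
from telocus.synthetic_data import (
    SimulationPlan,
    generate_reference,
    simulate_short_read_alignments,
)


@pytest.fixture(scope="session")
def reference():
    return generate_reference(SimulationPlan(), seed=1)


@pytest.fixture(scope="session")
def short_reads(reference):
    return simulate_short_read_alignments(reference, None, seed=2)


@pytest.fixture(scope="session")
def compartments(reference):
    return build_compartments(
        reference.genes, reference.chrom_lengths, reference.plan.flank_width
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
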