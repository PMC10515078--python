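import numpy as np
import pytest

from mtmedip.genome_io import CircularGenome
from mtmedip.motifs import pwm_from_counts
from mtmedip.synthetic import SimulationConfig, make_genome

ATF4_CORE = "TGTTGGATCAGGAC"


@pytest.fixture(scope="session")
def core_pwm():
    """Near-deterministic PWM for the conserved ATF4 core site."""
    counts = np.zeros((4, len(ATF4_CORE)))
    for i, b in enumerate(ATF4_CORE):
        counts["ACGT".index(b), i] = 20.0
    return pwm_from_counts("ATF4core", counts, pseudocount=0.1)


@pytest.fixture(scope="session")
def small_genome():
    """3 kb seeded circular genome at the avian mtDNA base composition."""
    return make_genome(SimulationConfig(seed=42, genome_length=3000))


@pytest.fixture()
def toy_genome():
    return CircularGenome(id="toy", sequence="TACATCGGCATTACGCGGAT", circular=True)
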