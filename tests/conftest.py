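import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cnvrpipe import CnvCall, SimulationConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def small_cfg():
    """A fast-to-simulate herd: ~60 animals, 20 regions on two chromosomes."""
    return SimulationConfig(
        n_founders=20,
        n_generations=2,
        offspring_per_mating=2,
        chromosome_lengths={"1": 50_000_000, "2": 40_000_000},
        n_regions=20,
        region_mean_length=100_000,
        carrier_freq_range=(0.1, 0.3),
        seed=11,
    )


def make_call(chrom="1", start=100, end=200, cn=1, sample="S1", n_snps=5):
    return CnvCall(
        sample_id=sample, chromosome=str(chrom), start=start, end=end,
        copy_state=cn, n_snps=n_snps,
    )


@pytest.fixture
def toy_pedigree():
    """Two founders, two full-sib offspring, one inbred full-sib-mating child."""
    return pd.DataFrame(
        {
            "animal": ["F1", "F2", "C1", "C2", "I1"],
            "sire": ["0", "0", "F1", "F1", "C1"],
            "dam": ["0", "0", "F2", "F2", "C2"],
        }
    )
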