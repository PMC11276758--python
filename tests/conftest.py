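import numpy as np
import pytest

from parfusion.model import Chrom, FusionScenario, Haplotype, Individual, SimParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240723)


@pytest.fixture
def small_params():
    """A fast parameter set for structural tests."""
    return SimParams(
        scenario=FusionScenario.Y_NONPAR,
        s=0.3,
        h=0.5,
        r=0.1,
        mu=1e-2,
        N=100,
        generations=30,
        seed=7,
        replicates=4,
    )


def hap(chrom="X", fused=False, allele=0) -> Haplotype:
    return Haplotype(Chrom(chrom), fused, allele)


def ind(maternal, paternal) -> Individual:
    return Individual(maternal, paternal)


@pytest.fixture
def make_hap():
    return hap


@pytest.fixture
def make_ind():
    return ind
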