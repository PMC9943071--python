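import numpy as np
import pytest

from paleodel import archaic_depth as ad
from paleodel import synth


@pytest.fixture(scope="session")
def small_config():
    return synth.SynthConfig(n_deletions=150, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return synth.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_reads(small_cohort):
    return synth.generate_archaic_reads(small_cohort)


@pytest.fixture(scope="session")
def small_presence(small_cohort, small_reads):
    windows = [ad.DeletionWindow(d.chrom, d.start, d.end, d.id)
               for d in small_cohort.deletions]
    table = ad.genotype_windows(small_reads, windows)
    return ad.presence_matrix(table)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
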