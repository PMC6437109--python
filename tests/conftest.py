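import numpy as np
import pytest

import fcgrlocus as F
from fcgrlocus.locus_model import ChromosomeHaplotype, HaplotypeFrequencyTable


@pytest.fixture(scope="session")
def locus():
    return F.default_locus()


@pytest.fixture(scope="session")
def eur_pool():
    return F.default_pool("EUR")


BASE_ALLELES = {
    "FCGR2A_H131R": ("R",),
    "FCGR2A_Q27W": ("Q",),
    "FCGR3A_V158F": ("F",),
    "FCGR2C": ("Stop",),
    "FCGR2C_prom": ("2B.1",),
    "FCGR3B_NA": ("NA2",),
    "FCGR2B_prom": ("2B.1",),
    "FCGR2B_I232T": ("I",),
}


def make_hap(locus, cnr_copies=None, **overrides):
    """A baseline chromosome with selected variant alleles overridden.

    For duplicated/deleted CNRs the caller must override every variant on
    the affected genes with tuples of the right length.
    """
    alleles = dict(BASE_ALLELES)
    for k, v in overrides.items():
        alleles[k] = tuple(v) if isinstance(v, (tuple, list)) else (v,)
    return ChromosomeHaplotype(cnr_copies or {}, alleles, locus)


@pytest.fixture(scope="session")
def biallelic_pool(locus):
    """Two-haplotype pool differing only at FCGR2A H131R, frequency 1/2."""
    return HaplotypeFrequencyTable(
        {
            make_hap(locus, FCGR2A_H131R="H"): 0.5,
            make_hap(locus, FCGR2A_H131R="R"): 0.5,
        }
    )


def rng(seed=0):
    return np.random.default_rng(seed)
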