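"""Shared fixtures: small conformer pools reused across test modules."""

import numpy as np
import pytest

from mesokit import conformers as cf

SEQ60 = ("GASPLEKRV" * 7)[:60]


@pytest.fixture(scope="session")
def coil_pool():
    """40 statistical-coil conformers of a 60-residue chain."""
    return cf.build_pool(SEQ60, n=40, seed=11)


@pytest.fixture(scope="session")
def extended_pool(coil_pool):
    """Extended ('refined-style') subset of the coil pool plus strand rungs."""
    nu = coil_pool.nu
    idx = np.where(nu > np.median(nu))[0]
    return coil_pool.subset(idx)


@pytest.fixture(scope="session")
def strand_pool():
    """Fully strand-directed conformers (near-ideal extended rods)."""
    n = 60
    directive = cf.SecondaryStructureDirective(["strand"] * n, np.full(n, 9))
    return cf.build_pool(SEQ60, directive, n=5, seed=3)
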