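import numpy as np
import pytest

from maldihdx import PeptideFragment, basis_envelopes


@pytest.fixture(scope="session")
def angiotensin():
    """Angiotensin II, the classic 6-amide HDX calibration peptide."""
    return PeptideFragment("DRVYIHPF", name="angiotensinII")


@pytest.fixture(scope="session")
def ak1_107_117():
    """Adenylate kinase 1 peptic fragment 107-117 (9 exchangeable amides)."""
    return PeptideFragment("FERRIGQPTLL", name="107-117", range_start=107, range_end=117)


@pytest.fixture(scope="session")
def angiotensin_basis(angiotensin):
    return basis_envelopes(angiotensin, solvent_D_fraction=0.9)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
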