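import numpy as np
import pytest

from rbcneutron.msa import YukawaInteraction
from rbcneutron.sas_models import ButlerParams, GuinierPorodParams


@pytest.fixture(scope="session")
def horse_yukawa():
    """Charged-hard-sphere state of Hb in horse RBCs (physiological)."""
    return YukawaInteraction.from_physical(
        contact_potential=2.5, r_eff=23.6, phi=0.256, kappa_inv=7.8, T=293.0)


@pytest.fixture(scope="session")
def human_yukawa():
    return YukawaInteraction.from_physical(
        contact_potential=3.3, r_eff=22.6, phi=0.249, kappa_inv=7.8, T=293.0)


@pytest.fixture(scope="session")
def butler_truth():
    """Rouleaux correlation-peak morphology of RBCs in isotonic saline."""
    return ButlerParams(I0=1.0, alpha=0.1, xi=4.61, d=3.6)


@pytest.fixture(scope="session")
def gp_truth():
    """Shrunken-sphere morphology of valinomycin-treated RBCs."""
    return GuinierPorodParams(scale=1.0, Rg=1.15, d=3.9)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
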