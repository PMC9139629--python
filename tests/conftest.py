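import numpy as np
import pytest

from smrisk import DVH
from smrisk.dasu import default_dasu_registry
from smrisk.schneider import default_schneider_registry


@pytest.fixture(scope="session")
def dasu_registry():
    return default_dasu_registry()


@pytest.fixture(scope="session")
def schneider_registry():
    return default_schneider_registry()


@pytest.fixture
def uniform_dvh():
    """Factory for single-bin (uniform dose) DVHs."""

    def make(dose, n_fractions=1, organ="lung"):
        return DVH(
            organ_name=organ,
            bin_dose=np.array([float(dose)]),
            bin_volume_fraction=np.array([1.0]),
            n_fractions=n_fractions,
        )

    return make


@pytest.fixture
def random_dvh():
    """Factory for random normalized multi-bin differential DVHs.

    Draws a zero-dose bin plus sorted positive doses with Dirichlet
    volume fractions — structurally like a clinical organ DVH.
    """

    def make(rng, n_bins=30, max_dose=60.0, n_fractions=27, organ="lung"):
        doses = np.sort(rng.uniform(0.1, max_dose, size=n_bins))
        vols = rng.dirichlet(np.ones(n_bins + 1))
        return DVH(
            organ_name=organ,
            bin_dose=np.concatenate(([0.0], doses)),
            bin_volume_fraction=vols,
            n_fractions=n_fractions,
        )

    return make
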