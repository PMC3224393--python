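import numpy as np
import pytest

from egfr_erk.network import build_reference_network, reference_variants
from egfr_erk.simulate import StimulusProtocol, simulate


@pytest.fixture(scope="session")
def network():
    return build_reference_network()


@pytest.fixture(scope="session")
def variants(network):
    return reference_variants(network)


@pytest.fixture(scope="session")
def trajectories_10nM(variants):
    """Full-grid 10 nM EGF trajectories for the three blotted cell lines."""
    proto = StimulusProtocol(egf_dose=10.0)
    return {
        name: simulate(variants[name], proto)
        for name in ("WT", "EGFR_WT", "L858R_A")
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
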