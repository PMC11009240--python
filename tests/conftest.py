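import warnings

import numpy as np
import pandas as pd
import pytest

from thermosol import simulate as sim
from thermosol.psup import MixingRatioModel

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def reference_fractionation():
    """2000-protein fractionation experiment at the reference conditions.

    alpha_s = 0.7, alpha_p = 1.4, sigma = 0.1 under the default two-class
    (condenser / non-condenser) scenario.
    """
    scenario = sim.default_scenario(2000)
    quant, truth = sim.simulate_fractionation(
        scenario, alpha_s=0.7, alpha_p=1.4, sigma=0.1, seed=11
    )
    return quant, truth


@pytest.fixture(scope="session")
def reference_posterior(reference_fractionation):
    """Shared MCMC fit of the reference experiment (reused across tests)."""
    quant, _ = reference_fractionation
    return MixingRatioModel(quant).fit(seed=5)


@pytest.fixture
def toy_quant():
    """Five-record fractionation table with moderate intensities."""
    return pd.DataFrame(
        {
            "protein_id": [f"p{i}" for i in range(5)],
            "total": [10.0, 25.0, 7.0, 40.0, 18.0],
            "sup": [6.0, 10.0, 2.0, 30.0, 9.0],
            "pellet": [4.0, 14.0, 5.0, 8.0, 8.0],
        }
    )


@pytest.fixture
def sine_profile():
    """Smooth per-site exchange-fraction profile over 300 residues."""
    return np.clip(0.5 + 0.3 * np.sin(np.arange(300) / 15.0), 0.0, 1.0)
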