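import numpy as np
import pytest

from mermaidkin import kinetics, synth
from mermaidkin.solutions import SolutionComposition


@pytest.fixture(scope="session")
def ephys_scheme():
    return synth.ephys_scheme("mermaid1_ephys")


@pytest.fixture(scope="session")
def three_state():
    return synth.three_state_scheme("mermaid1_ephys")


@pytest.fixture(scope="session")
def spectro_scheme():
    return synth.spectro_scheme("mermaid1_spectro")


@pytest.fixture(scope="session")
def flash_protocol():
    return kinetics.LightProtocol(delta_flash=(0.0, 1.0))


@pytest.fixture(scope="session")
def flash_trajectory(ephys_scheme, flash_protocol):
    grid = np.linspace(0.0, 0.03, 300001)
    return kinetics.propagate(ephys_scheme, flash_protocol, grid)


@pytest.fixture(scope="session")
def kgluconate_internal():
    return SolutionComposition(
        components=(
            ("K-gluconate", 135.0),
            ("MgCl2", 4.0),
            ("Na2-ATP", 4.0),
            ("Na-GTP", 0.4),
            ("Na2-phosphocreatine", 10.0),
            ("ascorbate", 3.0),
            ("EGTA", 0.2),
            ("HEPES", 10.0),
        ),
        ph=7.2,
        temperature_c=25.0,
        label="K-gluconate internal",
    )


@pytest.fixture(scope="session")
def acsf_bath():
    return SolutionComposition(
        components=(
            ("NaCl", 135.0),
            ("KCl", 2.5),
            ("CaCl2", 2.0),
            ("MgCl2", 1.0),
            ("Na-HEPES", 10.0),
            ("d-glucose", 12.5),
            ("NaH2PO4", 1.25),
        ),
        ph=7.4,
        temperature_c=25.0,
        label="ACSF",
    )
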