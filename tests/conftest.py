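import numpy as np
import pytest

from tcsoil.design import TreatmentDesign
from tcsoil.simulate import SimulationConfig, generate_experiment


@pytest.fixture(scope="session")
def small_sim():
    """One small synthetic experiment shared by read-only tests."""
    return generate_experiment(SimulationConfig(seed=11, otu_depth=5000))


@pytest.fixture()
def design_rows():
    rows = []
    for sown in (False, True):
        for tc in (0.0, 100.0):
            for g in (0.0, 4.0):
                for day in (25, 50):
                    for rep in (1, 2):
                        d = TreatmentDesign("", tc, g, sown, day, rep)
                        rows.append(TreatmentDesign(
                            f"{d.variant_code}_d{day}_r{rep}", tc, g, sown, day, rep))
    return rows


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
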