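import numpy as np
import pandas as pd
import pytest

import floodmet as fm


@pytest.fixture(scope="session")
def soybean_model():
    """The packaged soybean network (synthetic parameterization)."""
    return fm.build_model(fm.soybean_network())


@pytest.fixture(scope="session")
def baseline_profile(soybean_model):
    return fm.simulate_profiles(soybean_model)


@pytest.fixture(scope="session")
def soybean_scan(soybean_model):
    """Full 15 x 16 modification scan of the packaged network."""
    return fm.modification_scan(soybean_model)


def make_chain(vmaxes=(100.0, 200.0, 190.0, 500.0), inits=(50.0, 30.0, 20.0)):
    """source -> A -> B -> C -> sink linear chain."""
    pools = [
        {"id": p, "name": p, "initial_amount": float(v), "is_target_fitting": True}
        for p, v in zip("ABC", inits)
    ]
    reactions = [
        {"id": "SRC", "substrates": [], "products": [["A", 1.0]], "km": {},
         "vmax": vmaxes[0], "pathway": "linker"},
        {"id": "T1", "substrates": [["A", 1.0]], "products": [["B", 1.0]],
         "km": {"A": 50.0}, "vmax": vmaxes[1], "pathway": "glycolysis",
         "modifiable": True},
        {"id": "T2", "substrates": [["B", 1.0]], "products": [["C", 1.0]],
         "km": {"B": 30.0}, "vmax": vmaxes[2], "pathway": "glycolysis",
         "modifiable": True},
        {"id": "SINK", "substrates": [["C", 1.0]], "products": [], "km": {"C": 100.0},
         "vmax": vmaxes[3], "pathway": "linker"},
    ]
    return fm.build_model({"pools": pools, "reactions": reactions})


@pytest.fixture
def chain_model():
    return make_chain()


def profile_from_arrays(days, columns):
    """Build a TemporalProfile directly from arrays (testing helper)."""
    return fm.TemporalProfile(
        amounts=pd.DataFrame(columns, index=pd.Index(np.asarray(days, float), name="day"))
    )
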