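import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import olfmap as om

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_panel():
    return om.generate_panel(4, 5, seed=7)


@pytest.fixture(scope="session")
def small_model(small_panel):
    return om.generate_model(small_panel, n_classes=12, n_groups=3,
                             within_group_gain=6.0, seed=7)


@pytest.fixture(scope="session")
def small_trains(small_model):
    return om.simulate_spike_trains(small_model, n_trials=2,
                                    n_sisters_per_class=2, seed=7)


@pytest.fixture(scope="session")
def small_matrix(small_trains):
    return om.build_response_matrix(small_trains, aggregation="first_round")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, class_ids=None, odor_ids=None, neuron_type="PN",
                glomeruli=None):
    """Hand-rolled ResponseMatrix for small explicit examples."""
    values = np.asarray(values, dtype=float)
    n_c, n_o = values.shape
    class_ids = class_ids or [f"C{i}" for i in range(n_c)]
    odor_ids = odor_ids or [f"o{j}" for j in range(n_o)]
    glomeruli = glomeruli or class_ids
    frame = pd.DataFrame(values, index=class_ids, columns=odor_ids)
    meta = pd.DataFrame({"glomerulus": glomeruli, "neuron_type": neuron_type},
                        index=frame.index)
    return om.ResponseMatrix(frame=frame, row_meta=meta)
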