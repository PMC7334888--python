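import numpy as np
import pytest
from hypothesis import settings

import vdjsim as vs

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def germline_set():
    """Small IGH-like synthetic reference shared across tests."""
    return vs.generate_synthetic_germline_set(8, 4, 3, seed=11)


@pytest.fixture(scope="session")
def nolocus_set():
    """Light-chain-like reference without D segments."""
    return vs.generate_synthetic_germline_set(6, 0, 3, seed=13)


@pytest.fixture(scope="session")
def small_repertoire(germline_set):
    """150 simulated sequences with non-uniform gene usage."""
    cfg = vs.make_default_config(
        germline_set, n_sequences=150, seed=7,
        v_freq=vs.geometric_frequency_table(germline_set.v_genes),
        d_freq=vs.geometric_frequency_table(germline_set.d_genes),
        j_freq=vs.geometric_frequency_table(germline_set.j_genes))
    return vs.simulate_repertoire(cfg)


@pytest.fixture
def fresh_repertoire(germline_set):
    """A private copy safe for in-place modification."""
    cfg = vs.make_default_config(germline_set, n_sequences=80, seed=23)
    return vs.simulate_repertoire(cfg)


def toy_repertoire(junctions, chain="IGH"):
    """Minimal records around given junction_aa strings (no event traces)."""
    records = [
        vs.SequenceRecord(sequence_id=f"s{i}", sequence_nt="NNN",
                          sequence_aa="X", junction_nt="NNN", junction_aa=j,
                          v_call="V", j_call="J", chain=chain)
        for i, j in enumerate(junctions)
    ]
    return vs.Repertoire(records=records)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
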