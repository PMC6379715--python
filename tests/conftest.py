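import numpy as np
import pytest

from quadfold.folds import get_fold
from quadfold.synth import GeneratorParams, build_ideal_structure


@pytest.fixture(scope="session")
def tp3_t6_topology():
    return get_fold("tp3_t6")


@pytest.fixture(scope="session")
def tp3_t6_structure(tp3_t6_topology):
    """Ideal all-atom TP3-T6 model (built once per session)."""
    return build_ideal_structure(tp3_t6_topology, GeneratorParams())


@pytest.fixture(scope="session")
def tp3_t6_peaks(tp3_t6_structure):
    from quadfold.noe import predict_peaks

    return predict_peaks(tp3_t6_structure)


@pytest.fixture(scope="session")
def tp3_t6_restraints(tp3_t6_topology, tp3_t6_peaks):
    from quadfold.restraints import TP3_T6_ABSENT_CONTACTS, assemble

    return assemble(
        tp3_t6_topology, peaks=tp3_t6_peaks, absent_contacts=TP3_T6_ABSENT_CONTACTS
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231215)
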