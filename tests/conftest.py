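import numpy as np
import pytest

from contactfes.contact_cv import build_contact_set
from contactfes.synthetic import (
    make_two_state_references,
    make_toy_chain,
    random_two_state_spec,
)


@pytest.fixture(scope="session")
def two_state():
    """A verified two-state fixture: ensembles, references and manifest."""
    spec = random_two_state_spec(seed=3)
    ens_in, ens_ac, ref_in, ref_ac, manifest = make_two_state_references(spec)
    return {
        "spec": spec, "ens_in": ens_in, "ens_ac": ens_ac,
        "ref_in": ref_in, "ref_ac": ref_ac, "manifest": manifest,
    }


@pytest.fixture(scope="session")
def contact_set(two_state):
    return build_contact_set(two_state["ens_in"], two_state["ens_ac"],
                             two_state["ref_in"], two_state["ref_ac"])


@pytest.fixture(scope="session")
def toy_chain():
    return make_toy_chain(10, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
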