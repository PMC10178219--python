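import numpy as np
import pytest

from gpcrpocket.numbering import resolve
from gpcrpocket.geometry import LabeledPointSet
from gpcrpocket.synthetic import BundleSpec, make_bundle


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic 7TM bundle with its mapping and pocket definition."""
    return make_bundle(BundleSpec(seed=11))


@pytest.fixture(scope="session")
def surrogate_points(bundle):
    model, rmap, pocket = bundle
    resolved = resolve(rmap, model, pocket.surrogate_ids)
    return LabeledPointSet.from_resolved(resolved)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
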