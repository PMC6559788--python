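import numpy as np
import pytest

from gutchem.fingerprints import FP_NBITS, Fingerprint
from gutchem.synthetic import (
    FixtureSpec,
    generate_compounds,
    generate_descriptors,
    generate_enzyme_map,
    generate_side_effects,
    generate_uses,
)


def random_fingerprint(rng: np.random.Generator, density: float = 0.2) -> Fingerprint:
    return Fingerprint(rng.random(FP_NBITS) < density)


@pytest.fixture(scope="session")
def small_spec() -> FixtureSpec:
    return FixtureSpec(n_compounds=80, seed=11)


@pytest.fixture(scope="session")
def small_fixture(small_spec):
    """80 compounds in 4 planted clusters, with the true labels."""
    return generate_compounds(small_spec)


@pytest.fixture(scope="session")
def full_fixture(small_spec, small_fixture):
    """All five synthetic tables for the 80-compound fixture."""
    compounds, clusters = small_fixture
    return {
        "spec": small_spec,
        "compounds": compounds,
        "clusters": clusters,
        "side_effects": generate_side_effects(small_spec, compounds, clusters),
        "enzyme_map": generate_enzyme_map(small_spec, compounds, clusters),
        "descriptors": generate_descriptors(small_spec, compounds, clusters),
        "uses": generate_uses(small_spec, compounds),
    }
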