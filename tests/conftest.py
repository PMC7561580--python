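import numpy as np
import pandas as pd
import pytest

from traitshore import (
    AssemblyScenario,
    TraitTable,
    build_functional_space,
    generate_communities,
    generate_traits,
)


@pytest.fixture(scope="session")
def traits50():
    return generate_traits(50, rng_seed=1)


@pytest.fixture(scope="session")
def space50(traits50):
    return build_functional_space(traits50, m=4)


@pytest.fixture(scope="session")
def random_cm(traits50):
    return generate_communities(traits50, AssemblyScenario(rng_seed=2))


@pytest.fixture
def tiny_traits():
    """Three species; sp1/sp2 differ only in pneumatocysts."""
    df = pd.DataFrame(
        {
            "sta": [50.0, 50.0, 80.0],
            "sa_v": [20.0, 20.0, 35.0],
            "thickness": [0.5, 0.5, 0.2],
            "tdmc": [0.2, 0.2, 0.4],
            "c_n": [15.0, 15.0, 25.0],
            "length": [10.0, 10.0, 40.0],
            "pneumatocysts": [0.0, 1.0, 0.0],
            "branching_order": [2.0, 2.0, 5.0],
            "sa_p": [5.0, 5.0, 2.0],
        },
        index=["sp1", "sp2", "sp3"],
    )
    return TraitTable(df)


def euclidean_distance_matrix(points):
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(np.asarray(points, float)))
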