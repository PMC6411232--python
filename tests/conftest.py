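import math

import numpy as np
import pytest

from maxentchemo import (
    BiomassRateDef,
    MetabolicNetwork,
    ToyParams,
    toy_medium,
    toy_network,
    toy_toxicity,
)


@pytest.fixture(scope="session")
def params():
    return ToyParams()


@pytest.fixture(scope="session")
def toy_net():
    return toy_network()


@pytest.fixture(scope="session")
def toy_med():
    return toy_medium()


@pytest.fixture(scope="session")
def toy_tox():
    return toy_toxicity()


def toy_polygon_vertices(xi: float, p: ToyParams) -> list[tuple[float, float]]:
    """Independent oracle: vertices of the (v_g, v_atp) feasible polygon,
    listed counter-clockwise, from the inequality description
    0 <= g <= U, 2g <= a <= min(38g, 2g + 18R)."""
    U = p.V_g if xi == 0 else min(p.V_g, p.c_g / xi)
    verts = [(0.0, 0.0)]
    kink = p.R / 2
    if kink < U:
        verts.append((kink, 38 * kink))
        verts.append((U, 2 * U + 18 * p.R))
    else:
        verts.append((U, 38 * U))
    verts.append((U, 2 * U))
    # drop duplicates that appear for degenerate parameter choices
    out = []
    for v in verts:
        if not out or abs(v[0] - out[-1][0]) + abs(v[1] - out[-1][1]) > 1e-14:
            out.append(v)
    return out


@pytest.fixture(scope="session")
def two_path_network():
    """Two parallel routes from substrate to product with identical
    stoichiometry but costs 1 and 2; growth is the product sink flux."""
    S = np.array(
        [
            # cheap  dear  sink
            [-1.0, -1.0, 0.0],  # A (substrate, exchange)
            [1.0, 1.0, -1.0],  # B (product)
        ]
    )
    return MetabolicNetwork(
        metabolite_ids=["A", "B"],
        reaction_ids=["cheap", "dear", "sink"],
        stoich=S,
        reversible=np.zeros(3, dtype=bool),
        lb=np.zeros(3),
        ub=np.full(3, math.inf),
        exchange_ids=["A"],
        excretable={"A": False},
        cost=np.array([1.0, 2.0, 0.0]),
        budget=10.0,
        biomass_rate_def=BiomassRateDef(kind="reaction", reaction_id="sink"),
        split_map={r: (r, None, 1.0) for r in ["cheap", "dear", "sink"]},
    )
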