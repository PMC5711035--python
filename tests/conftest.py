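import numpy as np
import pytest

from cyclehop import (
    DynamicsParams,
    SyntheticSpec,
    build_coupling,
    generate_attractors,
    generate_expression,
    select_periodic,
)


@pytest.fixture(scope="session")
def attractors64():
    return generate_attractors(64, 8, seed=1)


@pytest.fixture(scope="session")
def attractors300():
    """Default-scale fixture: 300 genes, 8 states, like a yeast encoding."""
    return generate_attractors(300, 8, seed=2)


@pytest.fixture(scope="session")
def attractors60():
    """Small fixture for search tests."""
    return generate_attractors(60, 8, seed=5)


@pytest.fixture(scope="session")
def coupling300(attractors300):
    return build_coupling(attractors300, 0.3)


@pytest.fixture(scope="session")
def coupling60(attractors60):
    return build_coupling(attractors60, 0.3)


@pytest.fixture(scope="session")
def params():
    return DynamicsParams(T=0.035, update_prob=0.2, rng_seed=0)


@pytest.fixture(scope="session")
def default_expression():
    """The default synthetic time course (300 periodic + 700 noise genes)."""
    spec = SyntheticSpec(seed=11)
    matrix, truth = generate_expression(spec)
    return spec, matrix, truth


@pytest.fixture(scope="session")
def selected_fits(default_expression):
    """Two-pass periodic selection on the default fixture (computed once)."""
    _, matrix, _ = default_expression
    return select_periodic(matrix)


def signed_relative_biases(fits, truth):
    """Mean signed relative error of each recovered parameter over true positives."""
    indexed = truth.set_index("gene_id")
    rows = []
    for f in fits:
        row = indexed.loc[f.gene_id]
        if not row.is_periodic:
            continue
        dphi = (f.phi - row.phi + np.pi) % (2 * np.pi) - np.pi
        rows.append(
            [
                (f.a - row.a) / row.a,
                (f.b - row.b) / row.b,
                (f.omega - row.omega) / row.omega,
                dphi / (2 * np.pi),
                (f.x0 - row.x0) / row.x0,
            ]
        )
    return np.asarray(rows).mean(axis=0)
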