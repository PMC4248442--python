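import pytest

from feaspath import bidirectional_best_hits, normalize_expression
from feaspath.simulate import (
    FixtureConfig,
    generate_compound_map,
    generate_expression,
    generate_pathways,
    generate_pm_plates,
    generate_proteomes,
)


@pytest.fixture(scope="session")
def config():
    return FixtureConfig()


@pytest.fixture(scope="session")
def expression_fixture(config):
    """Normalized default expression array plus its ground truth."""
    expr, truth = generate_expression(config)
    return normalize_expression(expr), truth


@pytest.fixture(scope="session")
def pathway_fixture(config, expression_fixture):
    expr, truth = expression_fixture
    return generate_pathways(config, expr, expr_truth=truth)


@pytest.fixture(scope="session")
def plate_fixture(config):
    return generate_pm_plates(config)


@pytest.fixture(scope="session")
def compound_fixture(config, plate_fixture, expression_fixture):
    expr, _ = expression_fixture
    _, pm_truth = plate_fixture
    return generate_compound_map(config, pm_truth, expr)


@pytest.fixture(scope="session")
def proteome_fixture(config, expression_fixture):
    _, truth = expression_fixture
    return generate_proteomes(config, expr_truth=truth)


@pytest.fixture(scope="session")
def bbh_fixture(proteome_fixture):
    """BBH result on the default proteome pair (all-vs-all alignments)."""
    query, ref, truth = proteome_fixture
    return bidirectional_best_hits(query, ref, threshold=30.0), truth
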