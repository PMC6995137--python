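import pytest

from graftce.config import load_config
from graftce.model import DecisionTreeModel


@pytest.fixture(scope="session")
def base_config():
    """Packaged base-case configuration."""
    return load_config()


@pytest.fixture(scope="session")
def base_model(base_config):
    return DecisionTreeModel(base_config.parameters, base_config.model)


@pytest.fixture(scope="session")
def base_results(base_model):
    """Full-size base-case PSA (50,000 iterations, seed 1), shared across tests."""
    return base_model.fit(n_iter=50_000, seed=1)


@pytest.fixture(scope="session")
def scenario_table(base_config):
    """Full bias-scenario sweep at 50,000 iterations, seed 1."""
    from graftce.scenarios import BiasScenarioAnalysis

    analysis = BiasScenarioAnalysis(
        base_config.parameters, base_config.scenarios, base_config.model, base_config.population
    )
    return analysis.run(n_iter=50_000, seed=1)
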