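import pytest

import dermadose as dd


@pytest.fixture(scope="session")
def chemicals():
    """The nine shipped reference chemicals, by name."""
    return {c.name: c for c in dd.table1_chemicals()}


@pytest.fixture(scope="session")
def studies():
    """The nine shipped study designs, by chemical name."""
    return {d.chemical.name: d for d in dd.load_studies()}


@pytest.fixture(scope="session")
def sim_cache():
    """Session-wide cache so identical scenarios are simulated once."""
    return {}


@pytest.fixture(scope="session")
def simulate_cached(sim_cache):
    from dermadose.scenarios import _simulate_cached

    def run(scenario):
        return _simulate_cached(sim_cache, scenario)

    return run
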