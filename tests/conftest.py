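import pytest

from prosthoplan.chart import FindingsChart
from prosthoplan.generate import GeneratorConfig, generate_collection


@pytest.fixture(scope="session")
def small_collection():
    """A small but fully representative generated collection."""
    return generate_collection(GeneratorConfig(n_total=400, n_test=200, seed=7))


@pytest.fixture
def all_sufficient():
    return FindingsChart(["."] * 16)


def chart_with(**positions) -> FindingsChart:
    """All-sufficient chart with symbol overrides, e.g. chart_with(p5='f')."""
    sym = ["."] * 16
    for key, value in positions.items():
        sym[int(key[1:]) - 1] = value
    return FindingsChart(sym)
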