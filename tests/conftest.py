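import pytest

from lifeyears import AnalysisConfig, LifeYearsModel, load_registry


@pytest.fixture(scope="session")
def paper_table():
    return load_registry("paper-2018")


@pytest.fixture(scope="session")
def paper_results(paper_table):
    """Default evaluation: T* = 5 years, p = 1, both regions, full precision."""
    return LifeYearsModel(paper_table, AnalysisConfig()).fit()
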