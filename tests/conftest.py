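import pytest

from ovascreen.io import packaged_table1
from ovascreen.ndj import parse_screen_table, score_screen
from ovascreen.types import ScreenThresholds


@pytest.fixture(scope="session")
def thresholds():
    return ScreenThresholds()


@pytest.fixture(scope="session")
def table1_results():
    return parse_screen_table(packaged_table1())


@pytest.fixture(scope="session")
def table1_gene_calls(table1_results, thresholds):
    return score_screen(table1_results, thresholds)
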