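from pathlib import Path

import pandas as pd
import pytest

from nitrarisk import DEFAULT_GROUPS, assess, fixture_table2

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def survey_samples():
    """The packaged 66-well groundwater survey."""
    return fixture_table2()


@pytest.fixture(scope="session")
def survey_results(survey_samples):
    return assess(survey_samples, DEFAULT_GROUPS)


@pytest.fixture(scope="session")
def printed_table():
    """The published per-sample EDI/HQ table, as printed (4 d.p.)."""
    return pd.read_csv(DATA_DIR / "table2_printed.csv")
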