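from pathlib import Path

import pytest

from medfamilies import AnalysisConfig, load_table1_fixture, run_full_pipeline

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def default_config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def national_result(table1, default_config):
    """The full pipeline on the packaged national table, run once."""
    return run_full_pipeline(table1, default_config)


@pytest.fixture(scope="session")
def published_intervals():
    """Published per-family 95% credible bounds (inf., sup.), 4 decimals."""
    out = {}
    with (DATA_DIR / "table1_published_intervals.tsv").open() as fh:
        next(fh)
        for line in fh:
            family, low, high = line.rstrip("\n").split("\t")
            out[family] = (float(low), float(high))
    return out
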