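from pathlib import Path

import pytest

from implicon.config import AnalysisConfig
from implicon.panel import default_panel

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def peg3(panel):
    return next(r for r in panel if r.name == "Peg3")


@pytest.fixture(scope="session")
def gnas(panel):
    return next(r for r in panel if r.name == "Gnas")


@pytest.fixture(scope="session")
def ase_toy():
    """Hand-evaluated 20-gene shortlisting fixture (counts + expression)."""
    from implicon.ase import read_ase_tables

    return read_ase_tables(DATA_DIR / "ase_toy_counts.tsv",
                           DATA_DIR / "ase_toy_expr.tsv")
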