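from pathlib import Path

import pandas as pd
import pytest

from indelkit import build_table1_fixture, reconstruct_counts_from_summary
from indelkit.synthetic_data import TABLE1_N

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def published_table() -> pd.DataFrame:
    """The published per-locus report table (57 loci, all columns, 4 dp)."""
    return pd.read_csv(DATA / "table1_published.csv")


@pytest.fixture(scope="session")
def panel_counts(published_table):
    """Genotype counts reconstructed from each published row."""
    return [
        reconstruct_counts_from_summary(r.f_ins, r.ho, TABLE1_N)
        for r in published_table.itertuples()
    ]


@pytest.fixture(scope="session")
def fixture_matrix():
    """The deterministic 262 x 57 genotype matrix rebuilt from summaries."""
    return build_table1_fixture()
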