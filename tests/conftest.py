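import pandas as pd
import pytest

from randucla import EngineConfig, RatingScale
from randucla.datasets import moderator_panel_summaries


@pytest.fixture
def scale() -> RatingScale:
    return RatingScale()


@pytest.fixture
def config() -> EngineConfig:
    return EngineConfig()


@pytest.fixture(scope="session")
def summary_table() -> pd.DataFrame:
    """The published two-stage panel summary table (17 rows)."""
    return moderator_panel_summaries()


@pytest.fixture
def long_csv(tmp_path):
    """Factory writing a long-form ratings CSV from (item, rater, rating) rows."""

    def write(rows, name="ratings.csv"):
        path = tmp_path / name
        df = pd.DataFrame(rows, columns=["item", "rater", "rating"])
        df.to_csv(path, index=False)
        return path

    return write
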