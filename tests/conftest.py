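import pandas as pd
import pytest

from cdmdeid import SchemaRegistry


@pytest.fixture(scope="session")
def registry() -> SchemaRegistry:
    return SchemaRegistry.bundled()


@pytest.fixture
def person_frame():
    """Tiny PERSON-like frame with known QI structure (two classes of 2, one
    singleton) for partition/risk tests."""

    def make(rows=None) -> pd.DataFrame:
        rows = rows if rows is not None else [
            ("M", "K", "NH"),
            ("M", "K", "NH"),
            ("F", "K", "NH"),
            ("F", "K", "NH"),
            ("F", "J", "HI"),
        ]
        return pd.DataFrame(
            rows,
            columns=["gender_source_value", "race_source_value", "ethnicity_source_value"],
        )

    return make
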