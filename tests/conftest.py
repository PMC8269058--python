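import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from obptools import datasets

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def evidence() -> pd.DataFrame:
    """The bundled disulfide-evidence table."""
    return datasets.load_bridged_species()


@pytest.fixture(scope="session")
def evidence_by_protein(evidence) -> dict[str, pd.DataFrame]:
    return {name: sub for name, sub in evidence.groupby("protein")}
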