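import pandas as pd
import pytest

from offkin import datasets


@pytest.fixture(scope="session")
def plx_panel() -> pd.DataFrame:
    return datasets.load_panel("PLX4720")


@pytest.fixture(scope="session")
def vem_panel() -> pd.DataFrame:
    return datasets.load_panel("vemurafenib")


@pytest.fixture(scope="session")
def plx_profiles():
    return datasets.load_panel_profiles("PLX4720")


@pytest.fixture(scope="session")
def vem_profiles():
    return datasets.load_panel_profiles("vemurafenib")
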