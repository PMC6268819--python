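import numpy as np
import pandas as pd
import pytest

from cypcons import corpus, synthdata


@pytest.fixture(scope="session")
def training_records():
    return corpus.load_training_fixture()


@pytest.fixture(scope="session")
def training_frame():
    return corpus.training_frame()


@pytest.fixture(scope="session")
def extrapolation_rows():
    return corpus.load_extrapolation_fixture()


@pytest.fixture(scope="session")
def study():
    """One full synthetic study at default conditions (121 train / 120 ev)."""
    return synthdata.gen_study(synthdata.GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def study_mws(study):
    return pd.Series({r.identifier: r.mw for r in study.train_records})


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
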