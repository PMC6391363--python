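import dataclasses

import numpy as np
import pandas as pd
import pytest

from primeconflict import load_default_montage
from primeconflict.synth import default_components

DEMO16 = ("P7", "P8", "P9", "P10", "FCz", "PO1", "PO2", "TP10",
          "CP3", "CP4", "Fz", "Cz", "O1", "O2", "F3", "F4")


@pytest.fixture(scope="session")
def montage():
    return load_default_montage()


@pytest.fixture(scope="session")
def montage16(montage):
    return montage.subset(DEMO16)


@pytest.fixture(scope="session")
def montage8(montage):
    return montage.subset(("P7", "P8", "P9", "P10", "FCz", "PO1", "PO2", "TP10"))


@pytest.fixture(scope="session")
def null_components():
    """Standard component set with the PCE-linked scaling switched off."""
    return tuple(dataclasses.replace(c, pce_scaling_uv_per_ms=0.0)
                 for c in default_components())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def toy_trial_table(rows):
    """rows: (subject, compatibility, congruency, correct, rt_ms)."""
    return pd.DataFrame(rows, columns=["subject", "compatibility", "congruency",
                                       "correct", "rt_ms"])
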