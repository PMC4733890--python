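import numpy as np
import pytest

from retinosign.cli import RunConfig, analyze_table
from retinosign.rf_data import RFRecord, RFTable
from retinosign.synthetic import (conformal_patch, sample_penetrations,
                                  strip_cortex)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def three_strip_cortex():
    return strip_cortex(n_strips=3, strip_width=2.0, height=6.0, seed=3)


@pytest.fixture(scope="session")
def three_strip_table(three_strip_cortex):
    return sample_penetrations(three_strip_cortex, 0.5, 0.5, seed=3)


@pytest.fixture(scope="session")
def conformal_results():
    """Full pipeline on a noiseless conformal nonmirror patch."""
    cortex = conformal_patch()
    table = sample_penetrations(cortex, 0.25, 0.25)
    return cortex, analyze_table(table, RunConfig())


def make_table(rows, hemisphere="right", normalized=True):
    """Build an RFTable from (x, y, r, theta, l, w, phi) rows."""
    records = [
        RFRecord(x=x, y=y, r=r, theta=th, l=l, w=w, phi=phi, pen_id=i + 1)
        for i, (x, y, r, th, l, w, phi) in enumerate(rows)
    ]
    return RFTable(records=records, hemisphere=hemisphere,
                   normalized=normalized)
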