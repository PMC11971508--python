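import numpy as np
import pytest

from livert1.epg import build_spoiling_correction
from livert1.field_maps import DamLookup


@pytest.fixture(scope="session")
def corr_table_phantom():
    """Incomplete-spoiling correction for the agar phantom (T2 = 45 ms)."""
    return build_spoiling_correction(tr=4.1, t2=45.0, rf_spoil_increment=50.0)


@pytest.fixture(scope="session")
def dam_lookup():
    """Slice-profile DAM lookup for the 65/130 degree EPI protocol."""
    return DamLookup()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
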