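import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")

#: Default field values for a healthy nondiabetic man with every
#: measurement strictly inside the normal range.
RECORD_DEFAULTS = dict(
    subject_id="S1",
    age=40,
    sex="male",
    weight=75.0,
    height=1.75,
    waist=85.0,
    sbp=118.0,
    dbp=75.0,
    fpg=90.0,
    insulin=8.0,
    tg=110.0,
    hdl=45.0,
    tc=180.0,
    ldl_direct=np.nan,
    diabetes_history=False,
    antihypertensive_med=False,
    pregnant=False,
)


def make_cohort(*rows: dict) -> pd.DataFrame:
    """Build a cohort DataFrame from per-record field overrides."""
    out = []
    for i, row in enumerate(rows, start=1):
        rec = dict(RECORD_DEFAULTS, subject_id=f"S{i}")
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
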