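import datetime as dt

import numpy as np
import pytest

from lfqassess import CatchRecord, GrowthParameters, TrapSet


@pytest.fixture
def paper_growth() -> GrowthParameters:
    """Pooled-sex growth point estimates used throughout the worked examples."""
    return GrowthParameters(linf_mm=176.76, k_per_year=0.07)


def make_records(lengths, dates=None, set_id="S1", depth=100.0, sex="unknown",
                 weights=None):
    """Build CatchRecord lists from plain arrays (test helper)."""
    n = len(lengths)
    if dates is None:
        dates = [dt.date(2000, 7, 15)] * n
    if weights is None:
        weights = [None] * n
    return [
        CatchRecord(set_id=set_id, date=d, depth_m=depth, sex=sex,
                    cl_mm=float(L), ww_g=w)
        for L, d, w in zip(lengths, dates, weights)
    ]


@pytest.fixture
def small_survey():
    """Three trap sets and a handful of records, for CPUE bookkeeping tests."""
    sets = [
        TrapSet("A", dt.date(2000, 7, 10), 50.0, n_traps=15),
        TrapSet("B", dt.date(2000, 7, 11), 90.0, n_traps=15),
        TrapSet("C", dt.date(2000, 7, 12), 90.0, n_traps=10, valid=True),
    ]
    records = make_records([100.0] * 30, set_id="A") + make_records(
        [110.0] * 5, set_id="B"
    )
    for r in records:
        assert r.set_id in {"A", "B"}
    return sets, records
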