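import numpy as np
import pandas as pd
import pytest

from echinodev import CountMatrix, PresenceMatrix, TimeCourseMatrix

TIMEPOINTS = [9.0, 18.0, 27.0, 39.0]


@pytest.fixture
def small_counts() -> CountMatrix:
    """Three ECs with included totals 9, 10 and 250 over four samples."""
    counts = pd.DataFrame(
        {
            "S9hpf": [2, 3, 100],
            "S18hpf": [3, 3, 50],
            "S27hpf": [2, 2, 60],
            "S39hpf": [2, 2, 40],
        },
        index=pd.Index(["EC_a", "EC_b", "EC_c"], name="ec"),
    )
    meta = pd.DataFrame(
        {"hpf": TIMEPOINTS, "included": [True] * 4},
        index=pd.Index(counts.columns, name="sample"),
    )
    return CountMatrix(counts=counts, sample_meta=meta)


@pytest.fixture
def toy_timecourse() -> TimeCourseMatrix:
    values = pd.DataFrame(
        [[2.0, 4.0, 8.0, 4.0], [5.0, 5.0, 5.0, 5.0], [1.0, 0.99, 1.0, 1.0]],
        index=pd.Index(["EC_peak", "EC_flat", "EC_wobble"], name="ec"),
        columns=TIMEPOINTS,
    )
    return TimeCourseMatrix(values=values, unit="rpkm")


@pytest.fixture
def toy_presence() -> PresenceMatrix:
    """Five genes with patterns ABCD, ABCD, AB, AC, A (A = reference)."""
    present = pd.DataFrame(
        {
            "A": [True] * 5,
            "B": [True, True, True, False, False],
            "C": [True, True, False, True, False],
            "D": [True, True, False, False, False],
        },
        index=pd.Index([f"g{i}" for i in range(5)], name="gene"),
    )
    return PresenceMatrix(present=present)
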