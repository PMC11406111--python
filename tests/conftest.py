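import numpy as np
import pandas as pd
import pytest

from silicarisk.survival import ExposurePath, SubjectRecord


@pytest.fixture
def exposure_life_table() -> pd.DataFrame:
    """Published cohort life table: participants reaching each cumulative
    total-silica exposure bin (L), withdrawals (W) and silicosis cases (D)."""
    rows = [
        ("<=2.46", 2551, 221, 7),
        ("2.46-4.92", 2323, 290, 24),
        ("4.92-7.38", 2009, 578, 47),
        ("7.38-9.84", 1384, 570, 59),
        ("9.84-12.30", 755, 388, 60),
        ("12.30-14.76", 307, 124, 34),
        ("14.76-17.22", 149, 63, 10),
        ("17.22-19.68", 76, 25, 3),
        ("19.68-22.14", 48, 11, 1),
        ("22.14-24.60", 36, 14, 1),
        ("24.60-27.06", 21, 10, 1),
        ("27.06-29.52", 10, 7, 0),
        ("29.52-31.98", 3, 2, 0),
        (">31.98", 1, 1, 0),
    ]
    return pd.DataFrame(rows, columns=["bin", "L", "W", "D"])


def make_records(rows, rate=0.0):
    """rows: iterable of (exit_time, event, gender)."""
    return [
        SubjectRecord(
            subject_id=f"S{i}",
            gender=g,
            exit_time=float(t),
            event=e,
            path=ExposurePath.constant(rate),
        )
        for i, (t, e, g) in enumerate(rows)
    ]


@pytest.fixture
def toy_two_group():
    """Six subjects in two groups with a hand-checkable log-rank statistic."""
    rows = [(1, 1, 1), (3, 1, 1), (5, 0, 1), (2, 1, 0), (4, 0, 0), (6, 0, 0)]
    records = make_records(rows)
    groups = ["A", "A", "A", "B", "B", "B"]
    return records, groups
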