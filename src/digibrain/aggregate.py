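"""Collapse repeated measurements to one value per subject and variable.

Over the 24-week study every subject performed each active test many times
and attended three clinical visits and two MRI scans.  Aggregation reduces
variability and handles missing data: digital measures take the *median*
over all valid tests (even counts use the mean-of-middle convention, and
missing test-level values are ignored); clinical scores and regional MRI
outcomes take the arithmetic *mean* over available visits/scans.  A cell
with no observations stays missing; a subject with no MRI scans drops out
of the region table entirely.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import DIGITAL_MEASURE_NAMES, extract_record
from .streams import TestRecord


def extract_valid_tests(records: list[TestRecord],
                        per_shape: bool = False) -> pd.DataFrame:
    """Run feature extraction on every valid record.

    Returns a long table with one row per (subject, test administration)
    and one column per measure produced by that test type; invalid records
    are skipped.
    """
    rows = []
    for rec in records:
        if not rec.valid:
            continue
        row = {"subject_id": rec.subject_id, "test_type": rec.test_type,
               "start_time": rec.start_time}
        row.update(extract_record(rec, per_shape=per_shape))
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_digital(test_level: pd.DataFrame) -> pd.DataFrame:
    """Median over valid tests, per subject per digital measure.

    Parameters
    ----------
    test_level : DataFrame
        Long table as returned by :func:`extract_valid_tests`.

    Returns
    -------
    DataFrame indexed by subject_id with one column per measure; cells for
    which every test-level value is missing remain NaN.
    """
    if test_level.empty:
        return pd.DataFrame(columns=list(DIGITAL_MEASURE_NAMES))
    value_cols = [c for c in test_level.columns
                  if c not in ("subject_id", "test_type", "start_time")]
    return test_level.groupby("subject_id")[value_cols].median()


def aggregate_clinical(visits: pd.DataFrame) -> pd.DataFrame:
    """Mean over the (≤3) clinical visits, per subject per score."""
    cols = [c for c in visits.columns if c not in ("subject_id", "visit")]
    return visits.groupby("subject_id")[cols].mean()


def aggregate_mri(scans: pd.DataFrame) -> pd.DataFrame:
    """Mean over the (≤2) MRI scans; subjects with zero scans are absent."""
    cols = [c for c in scans.columns if c not in ("subject_id", "scan")]
    return scans.groupby("subject_id")[cols].mean()


def build_measure_table(digital: pd.DataFrame,
                        clinical: pd.DataFrame) -> pd.DataFrame:
    """Join aggregated digital and clinical measures into one table."""
    return digital.join(clinical, how="outer")


def median_ignore_missing(values) -> float:
    """Median with NaNs ignored; NaN when nothing remains."""
    arr = np.asarray(values, float)
    arr = arr[~np.isnan(arr)]
    return float(np.median(arr)) if len(arr) else np.nan
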