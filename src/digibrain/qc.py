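"""Test-validity quality control and the adherence inclusion filter.

Active tests were performed unsupervised, so two families of flags identify
administrations that do not reflect the instructed task: "play to quit"
(rushing through a test without performing it) and "device on table"
(gait/balance tests with the phone resting on a surface).  Any flagged test
is excluded; a test with no flags is a *valid test*.  Subjects are included
in the analysis only if they contributed on average at least 1.5 valid
tests per week (≈21% adherence under a daily schedule).

The exact flag thresholds used in the original deployment are not
published; the defaults here are documented reconstructions and are fully
configurable through :class:`QCThresholds`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from . import shapes as _shapes
from .streams import NOMINAL_DURATION, TestRecord

PLAY_TO_QUIT = "play_to_quit"
DEVICE_ON_TABLE = "device_on_table"
SCHEMA_INVALID = "schema_invalid"


@dataclass
class QCThresholds:
    """Configurable validity thresholds (all reconstructions)."""

    min_esdmt_responses: int = 3          # play-to-quit floor, e-SDMT
    min_draw_length_fraction: float = 0.2  # of total reference path length
    min_pinch_gestures: int = 1
    min_duration_fraction: float = 0.5    # gait/balance stream vs nominal
    stillness_variance: float = 1e-3      # (m/s²)², 2MWT / UTT on-table
    sbt_noise_floor_variance: float = 1e-6  # (m/s²)², SBT device noise floor

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "QCThresholds":
        return cls(**d)


def _gravity_removed_variance(stream) -> float:
    """Total variance of the mean-removed acceleration vector, (m/s²)²."""
    a = stream.accel - stream.accel.mean(axis=0)
    return float(np.mean(np.sum(a * a, axis=1)))


def flag_schema(record: TestRecord) -> str | None:
    """Flag records whose streams are missing or structurally invalid."""
    if record.test_type == "esdmt":
        if record.responses is None:
            return SCHEMA_INVALID
        return None
    if not record.streams:
        return SCHEMA_INVALID
    for st in record.streams:
        try:
            st.validate()
        except ValueError:
            return SCHEMA_INVALID
        if record.test_type in ("sbt", "2mwt", "utt") and st.modality != "inertial":
            return SCHEMA_INVALID
    return None


def flag_play_to_quit(record: TestRecord,
                      thresholds: QCThresholds | None = None) -> str | None:
    """Detect tests completed without performing the instructed task.

    The interaction-density floors are per test: fewer than 3 e-SDMT
    responses, a total drawn trace shorter than 20% of the reference
    shapes' path length, zero pinch gestures, or a gait/balance stream
    shorter than half the nominal test duration.
    """
    th = thresholds or QCThresholds()
    tt = record.test_type
    if tt == "esdmt":
        if record.responses is None or len(record.responses) < th.min_esdmt_responses:
            return PLAY_TO_QUIT
    elif tt == "draw":
        total = ref = 0.0
        for st in record.streams:
            pts = np.column_stack([st.x, st.y])
            total += float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
        ref = sum(_shapes.path_length(s) for s in _shapes.SHAPE_IDS)
        if total < th.min_draw_length_fraction * ref:
            return PLAY_TO_QUIT
    elif tt == "pinch":
        from .features import _pinch_gestures
        if not record.streams or \
                len(_pinch_gestures(record.streams[0])) < th.min_pinch_gestures:
            return PLAY_TO_QUIT
    else:  # sbt / 2mwt / utt
        if not record.streams:
            return PLAY_TO_QUIT
        dur = record.streams[0].duration
        if dur < th.min_duration_fraction * NOMINAL_DURATION[tt]:
            return PLAY_TO_QUIT
    return None


def flag_device_on_table(record: TestRecord,
                         thresholds: QCThresholds | None = None) -> str | None:
    """Detect gait/balance tests performed with the phone on a table.

    The gravity-removed acceleration variance over the whole test is
    compared with a stillness threshold: for the walking tests no genuine
    walk can be that still, and for the static balance test no human can
    hold the device below the hardware noise floor.  Non-inertial tests
    are a no-op.
    """
    th = thresholds or QCThresholds()
    if record.test_type not in ("sbt", "2mwt", "utt"):
        return None
    if not record.streams or record.streams[0].modality != "inertial":
        return None
    var = _gravity_removed_variance(record.streams[0])
    limit = th.sbt_noise_floor_variance if record.test_type == "sbt" \
        else th.stillness_variance
    return DEVICE_ON_TABLE if var < limit else None


def run_qc(records: list[TestRecord],
           thresholds: QCThresholds | None = None) -> list[TestRecord]:
    """Apply all flags in place; idempotent. Returns the same list."""
    th = thresholds or QCThresholds()
    for rec in records:
        flags = set()
        if (f := flag_schema(rec)) is not None:
            flags.add(f)
        else:
            if (f := flag_play_to_quit(rec, th)) is not None:
                flags.add(f)
            if (f := flag_device_on_table(rec, th)) is not None:
                flags.add(f)
        rec.flags = flags
        rec.qc_run = True
    return records


def adherence_filter(records: list[TestRecord], study_weeks: float | None = 24.0,
                     min_rate: float = 1.5) -> set[str]:
    """Subjects contributing ≥ ``min_rate`` valid tests per week on average.

    All active tests are pooled and the rate is averaged over the study
    window ``study_weeks`` (default 24); inclusion is inclusive at the
    boundary ("at least 1.5 per week"), and adding a valid test can never
    turn an included subject into an excluded one.  With
    ``study_weeks=None`` the observation window is instead the span from a
    subject's first to last record, floored at one week.  A subject with a
    zero observation window (or no valid tests at all) is excluded with a
    warning.
    """
    if study_weeks is not None and study_weeks <= 0:
        warnings.warn("zero observation window: all subjects excluded")
        return set()
    by_subject: dict[str, list[TestRecord]] = {}
    for rec in records:
        by_subject.setdefault(rec.subject_id, []).append(rec)
    included = set()
    for sid, recs in by_subject.items():
        if study_weeks is None:
            times = [r.start_time for r in recs]
            weeks = (max(times) - min(times)).total_seconds() / (7 * 86400)
            weeks = max(weeks, 1.0)
        else:
            weeks = study_weeks
        n_valid = sum(r.valid for r in recs)
        if n_valid == 0:
            warnings.warn(f"subject {sid}: no valid tests, excluded")
            continue
        if n_valid / weeks >= min_rate:
            included.add(sid)
    return included


def adherence_percent(min_rate: float = 1.5, tests_per_day: float = 1.0) -> float:
    """Adherence implied by a weekly valid-test rate under a daily schedule.

    With one scheduled test per day, 1.5 valid tests per week corresponds
    to 1.5/7 ≈ 21% adherence.
    """
    return 100.0 * min_rate / (7.0 * tests_per_day)
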