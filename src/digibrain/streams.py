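"""In-memory containers for raw sensor data and test administrations.

A :class:`SensorStream` holds the timestamped samples of one modality for a
single test administration: either touchscreen events (x, y, pointer id,
down/move/up phase) or triaxial accelerometer samples with an optional
yaw-rate channel.  Samples are stored as NumPy arrays, one row per event.

A :class:`TestRecord` bundles the streams (and, for the symbol–digit test,
the response log) of one administration of one active test together with
its quality-control state.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

#: Touch phase codes.
DOWN, MOVE, UP = 0, 1, 2
PHASE_NAMES = {DOWN: "down", MOVE: "move", UP: "up"}
PHASE_CODES = {v: k for k, v in PHASE_NAMES.items()}

#: The six active test types.
TEST_TYPES = ("esdmt", "draw", "pinch", "sbt", "2mwt", "utt")

#: Nominal test durations in seconds.
NOMINAL_DURATION = {"esdmt": 90.0, "draw": 60.0, "pinch": 30.0,
                    "sbt": 30.0, "2mwt": 120.0, "utt": 60.0}


@dataclass
class SensorStream:
    """Raw samples of one modality for one test administration.

    Exactly one family of payload arrays is populated depending on
    ``modality``: (``x``, ``y``, ``pointer_id``, ``phase``) for touch,
    (``accel``, optionally ``yaw_rate``) for inertial.  ``meta`` carries
    test-specific context, e.g. the drawn shape id or pinch target layout.
    """

    modality: str                      # "touch" | "inertial"
    t: np.ndarray                      # (n,) seconds, non-decreasing
    x: np.ndarray | None = None        # (n,) px
    y: np.ndarray | None = None        # (n,) px
    pointer_id: np.ndarray | None = None  # (n,) int
    phase: np.ndarray | None = None    # (n,) int codes DOWN/MOVE/UP
    accel: np.ndarray | None = None    # (n, 3) m/s²
    yaw_rate: np.ndarray | None = None  # (n,) rad/s
    meta: dict = field(default_factory=dict)

    # -- constructors -------------------------------------------------
    @classmethod
    def touch(cls, t, x, y, pointer_id, phase, meta=None) -> "SensorStream":
        return cls("touch", np.asarray(t, float), x=np.asarray(x, float),
                   y=np.asarray(y, float),
                   pointer_id=np.asarray(pointer_id, int),
                   phase=np.asarray(phase, int), meta=meta or {})

    @classmethod
    def inertial(cls, t, accel, yaw_rate=None, meta=None) -> "SensorStream":
        accel = np.asarray(accel, float)
        if accel.ndim != 2 or accel.shape[1] != 3:
            raise ValueError("accel must be an (n, 3) array")
        yr = None if yaw_rate is None else np.asarray(yaw_rate, float)
        return cls("inertial", np.asarray(t, float), accel=accel,
                   yaw_rate=yr, meta=meta or {})

    # -- basic properties ---------------------------------------------
    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Elapsed time from first to last sample, seconds."""
        return float(self.t[-1] - self.t[0]) if len(self.t) >= 2 else 0.0

    def validate(self) -> None:
        """Raise ValueError on schema violations.

        Checks monotone timestamps and, for touch streams, that every
        pointer's down/up phases are balanced.
        """
        if np.any(np.diff(self.t) < 0):
            raise ValueError("timestamps must be non-decreasing")
        if self.modality == "touch":
            for pid in np.unique(self.pointer_id):
                ph = self.phase[self.pointer_id == pid]
                if np.sum(ph == DOWN) != np.sum(ph == UP):
                    raise ValueError(
                        f"unbalanced down/up phases for pointer {pid}")
        elif self.modality != "inertial":
            raise ValueError(f"unknown modality {self.modality!r}")

    def time_shifted(self, dt: float) -> "SensorStream":
        """Copy with all timestamps (incl. time-like metadata) shifted by ``dt`` s."""
        meta = dict(self.meta)
        if "targets" in meta:
            meta["targets"] = [{**tg, "t_appear": tg["t_appear"] + dt}
                               for tg in meta["targets"]]
        return SensorStream(self.modality, self.t + dt, self.x, self.y,
                            self.pointer_id, self.phase, self.accel,
                            self.yaw_rate, meta)


@dataclass
class TestRecord:
    """One administration of one active test by one subject."""

    __test__ = False  # not a pytest test class despite the name

    subject_id: str
    test_type: str                     # one of TEST_TYPES
    start_time: _dt.datetime
    streams: list[SensorStream] = field(default_factory=list)
    #: e-SDMT response log: structured array with fields t (s) and correct.
    responses: np.ndarray | None = None
    flags: set = field(default_factory=set)
    qc_run: bool = False

    @property
    def valid(self) -> bool:
        """A test is valid iff quality control raised no flag."""
        return len(self.flags) == 0

    def __post_init__(self):
        if self.test_type not in TEST_TYPES:
            raise ValueError(f"unknown test type {self.test_type!r}")


def response_log(times, correct) -> np.ndarray:
    """Build an e-SDMT response log from parallel sequences."""
    log = np.zeros(len(times), dtype=[("t", float), ("correct", bool)])
    log["t"] = np.asarray(times, float)
    log["correct"] = np.asarray(correct, bool)
    return log[np.argsort(log["t"], kind="stable")]
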