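"""Digital measures extracted from raw smartphone sensor streams.

Sixteen measures quantify performance on the six active tests:

==================  ====================================  =======  ========
test                measure                               unit     better
==================  ====================================  =======  ========
e-SDMT              esdmt_n_correct                       count    higher
e-SDMT              esdmt_max_gap                         s        lower
e-SDMT              esdmt_sfi30                           —        higher
Draw a Shape        draw_accuracy                         —        higher
Draw a Shape        draw_celerity                         1/s      higher
Draw a Shape        draw_cv_linear / _angular / _radial   —        lower
Pinching            pinch_n_success                       count    higher
Pinching            pinch_gap_time                        s        lower
Pinching            pinch_asynchrony                      s        lower
Static Balance      sbt_sway_path                         m/s²     lower
U-Turn              utt_turn_speed                        rad/s    higher
2-Min Walk          walk_step_freq                        Hz       higher
2-Min Walk          walk_step_freq_var                    Hz²      lower
2-Min Walk          walk_step_power                       m²/s³    higher
==================  ====================================  =======  ========

The exact computational definitions are not standardized; the formulas here
are documented reconstructions (see docs/methods.md): waypoint-coverage
trace accuracy with a tolerance radius of 5% of the shape's bounding-box
diagonal, celerity = accuracy per unit drawing time, the speed fatigability
index as a last-30 s vs first-60 s correct-response rate ratio, sway path as
path length of the gravity-removed horizontal acceleration trajectory, and
step power as the mean per-step time-integral of squared detrended vertical
acceleration.  Medians are used for gap/asynchrony/turn aggregation within
a test for robustness.  Undefined values (e.g. no detected steps) are
returned as NaN and propagate as missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import signal as _sig
from scipy.spatial import cKDTree

from . import shapes as _shapes
from .streams import DOWN, MOVE, UP, SensorStream, TestRecord


# ---------------------------------------------------------------------------
# Measure registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasureInfo:
    name: str
    test: str
    unit: str
    higher_is_better: bool


DIGITAL_MEASURES: tuple[MeasureInfo, ...] = (
    MeasureInfo("esdmt_n_correct", "esdmt", "count", True),
    MeasureInfo("esdmt_max_gap", "esdmt", "s", False),
    MeasureInfo("esdmt_sfi30", "esdmt", "1", True),
    MeasureInfo("draw_accuracy", "draw", "1", True),
    MeasureInfo("draw_celerity", "draw", "1/s", True),
    MeasureInfo("draw_cv_linear", "draw", "1", False),
    MeasureInfo("draw_cv_angular", "draw", "1", False),
    MeasureInfo("draw_cv_radial", "draw", "1", False),
    MeasureInfo("pinch_n_success", "pinch", "count", True),
    MeasureInfo("pinch_gap_time", "pinch", "s", False),
    MeasureInfo("pinch_asynchrony", "pinch", "s", False),
    MeasureInfo("sbt_sway_path", "sbt", "m/s2", False),
    MeasureInfo("utt_turn_speed", "utt", "rad/s", True),
    MeasureInfo("walk_step_freq", "2mwt", "Hz", True),
    MeasureInfo("walk_step_freq_var", "2mwt", "Hz2", False),
    MeasureInfo("walk_step_power", "2mwt", "m2/s3", True),
)

CLINICAL_MEASURES: tuple[MeasureInfo, ...] = (
    MeasureInfo("edss", "clinical", "score", False),
    MeasureInfo("oral_sdmt", "clinical", "count", True),
    MeasureInfo("hpt9", "clinical", "s", False),
    MeasureInfo("t25fw", "clinical", "s", False),
    MeasureInfo("berg_balance", "clinical", "score", True),
)

MEASURE_INFO: dict[str, MeasureInfo] = {
    m.name: m for m in DIGITAL_MEASURES + CLINICAL_MEASURES}
DIGITAL_MEASURE_NAMES = tuple(m.name for m in DIGITAL_MEASURES)
CLINICAL_MEASURE_NAMES = tuple(m.name for m in CLINICAL_MEASURES)


def _cv(values: np.ndarray) -> float:
    """Coefficient of variation SD/mean (population SD); NaN if mean is 0."""
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    if len(values) < 2:
        return np.nan
    mean = values.mean()
    if mean == 0:
        return np.nan
    return float(values.std(ddof=0) / mean)


# ---------------------------------------------------------------------------
# e-SDMT
# ---------------------------------------------------------------------------

class EsdmtResult(NamedTuple):
    n_correct: int
    max_gap: float
    sfi30: float


def compute_esdmt(responses: np.ndarray, duration: float = 90.0) -> EsdmtResult:
    """Score one symbol–digit matching test from its response log.

    Parameters
    ----------
    responses : structured array with fields ``t`` (s) and ``correct``
        One row per submitted response, times relative to test start.
    duration : float
        Test length in seconds (default 90).

    Returns
    -------
    EsdmtResult
        ``n_correct`` — number of correct responses;
        ``max_gap`` — largest inter-arrival time between consecutive correct
        responses (0 by convention with fewer than two correct responses);
        ``sfi30`` — speed fatigability index, the correct-response rate of
        the final 30 s divided by that of the first 60 s (0 when the
        first-60 s rate is 0; values near 1 indicate sustained speed).
    """
    t = np.asarray(responses["t"], float)
    if np.any((t < 0) | (t > duration)):
        raise ValueError("response timestamp outside [0, duration]")
    tc = np.sort(t[np.asarray(responses["correct"], bool)])
    n_correct = len(tc)
    max_gap = float(np.max(np.diff(tc))) if n_correct >= 2 else 0.0
    split = duration - 30.0
    rate_first = np.sum(tc <= split) / split
    rate_last = np.sum(tc > split) / 30.0
    sfi30 = float(rate_last / rate_first) if rate_first > 0 else 0.0
    return EsdmtResult(n_correct, max_gap, sfi30)


# ---------------------------------------------------------------------------
# Draw a Shape
# ---------------------------------------------------------------------------

class DrawShapeResult(NamedTuple):
    accuracy: float
    celerity: float
    cv_linear: float
    cv_angular: float
    cv_radial: float


def compute_draw_shape(stream: SensorStream, shape: str,
                       tolerance_fraction: float = 0.05) -> DrawShapeResult:
    """Score one drawn shape against its reference polyline.

    Accuracy is the fraction of reference waypoints having at least one
    trace sample within the tolerance radius; celerity is accuracy divided
    by the drawing time (1/s).  Velocity smoothness is summarized by the
    coefficient of variation of the segmentwise linear speed and, for round
    shapes only, of the magnitudes of angular and radial velocity about the
    reference shape's centroid (NaN for lines and the square).
    """
    if stream.modality != "touch":
        raise ValueError("draw scoring requires a touch stream")
    if len(stream) < 2:
        raise ValueError("need at least 2 touch samples")
    pts = np.column_stack([stream.x, stream.y])
    t = stream.t
    draw_time = float(t[-1] - t[0])
    if draw_time <= 0:
        raise ValueError("zero total drawing time")

    ref = _shapes.waypoints(shape)
    tol = _shapes.tolerance_radius(shape, tolerance_fraction)
    dist, _ = cKDTree(pts).query(ref)
    accuracy = float(np.mean(dist <= tol))
    celerity = accuracy / draw_time

    dt = np.diff(t)
    ok = dt > 0
    seg = np.diff(pts, axis=0)
    v_lin = np.linalg.norm(seg[ok], axis=1) / dt[ok]
    cv_linear = _cv(v_lin)

    if shape in _shapes.ROUND_SHAPES:
        c = _shapes.centroid(shape)
        rel = pts - c
        theta = np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
        radius = np.linalg.norm(rel, axis=1)
        v_ang = np.abs(np.diff(theta)[ok] / dt[ok])
        v_rad = np.abs(np.diff(radius)[ok] / dt[ok])
        cv_angular = _cv(v_ang)
        cv_radial = _cv(v_rad)
    else:
        cv_angular = cv_radial = np.nan
    return DrawShapeResult(accuracy, celerity, cv_linear, cv_angular, cv_radial)


# ---------------------------------------------------------------------------
# Pinching
# ---------------------------------------------------------------------------

class PinchResult(NamedTuple):
    n_success: int
    gap_time: float
    asynchrony: float


def _pinch_gestures(stream: SensorStream):
    """Split a two-pointer touch stream into gestures.

    A gesture is one pinch attempt: the interval during which two pointers
    are concurrently on the screen.  Returns a list of dicts with per-pointer
    down times/positions, last positions, and the gesture time span.
    """
    t, pid, ph = stream.t, stream.pointer_id, stream.phase
    downs = np.flatnonzero(ph == DOWN)
    # pair pointer downs that overlap in time: greedy sweep over down events
    gestures = []
    used = np.zeros(len(downs), bool)
    # per-pointer up time for each down event
    up_time = np.full(len(downs), np.nan)
    for k, i in enumerate(downs):
        later = np.flatnonzero((ph == UP) & (pid == pid[i]) & (t >= t[i]))
        if len(later):
            up_time[k] = t[later[0]]
    for k, i in enumerate(downs):
        if used[k]:
            continue
        for m in range(k + 1, len(downs)):
            j = downs[m]
            if used[m] or pid[j] == pid[i]:
                continue
            if t[j] <= (up_time[k] if np.isfinite(up_time[k]) else np.inf):
                used[k] = used[m] = True
                t_end = np.nanmax([up_time[k], up_time[m]])
                sel = (t >= min(t[i], t[j])) & (t <= t_end)
                g = {
                    "t_down": (t[i], t[j]),
                    "p_down": (np.array([stream.x[i], stream.y[i]]),
                               np.array([stream.x[j], stream.y[j]])),
                    "start": float(min(t[i], t[j])),
                    "end": float(t_end),
                    "idx": (np.flatnonzero(sel & (pid == pid[i])),
                            np.flatnonzero(sel & (pid == pid[j]))),
                }
                gestures.append(g)
                break
    return gestures


def compute_pinching(stream: SensorStream, duration: float = 30.0) -> PinchResult:
    """Score one 30-s pinching test.

    A gesture is successful when both pointers land within the active
    target's radius and the pointers converge (inter-pointer distance
    decreases over the gesture).  ``n_success`` counts successful pinches;
    ``gap_time`` is the median interval from the end of one gesture to the
    start of the next; ``asynchrony`` is the median absolute offset between
    the two pointers' screen-contact times over successful pinches.  With no
    gestures, gap time and asynchrony are NaN (missing), not 0.
    """
    if stream.modality != "touch":
        raise ValueError("pinch scoring requires a touch stream")
    gestures = _pinch_gestures(stream)
    targets = stream.meta.get("targets", [])

    def active_target(t0):
        cand = [tg for tg in targets if tg["t_appear"] <= t0]
        return cand[-1] if cand else None

    n_success = 0
    asynchronies = []
    for g in gestures:
        tg = active_target(g["start"])
        hit = True
        if tg is not None:
            ctr = np.array([tg["x"], tg["y"]])
            hit = all(np.linalg.norm(p - ctr) <= tg["r"] for p in g["p_down"])
        ia, ib = g["idx"]
        converge = True
        if len(ia) and len(ib):
            pa = np.column_stack([stream.x[ia], stream.y[ia]])
            pb = np.column_stack([stream.x[ib], stream.y[ib]])
            m = min(len(pa), len(pb))
            d = np.linalg.norm(pa[:m] - pb[:m], axis=1)
            converge = d[-1] < d[0]
        if hit and converge:
            n_success += 1
            asynchronies.append(abs(g["t_down"][0] - g["t_down"][1]))

    if not gestures:
        return PinchResult(0, np.nan, np.nan)
    gaps = [gestures[k + 1]["start"] - gestures[k]["end"]
            for k in range(len(gestures) - 1)]
    gap_time = float(np.median(gaps)) if gaps else np.nan
    asyn = float(np.median(asynchronies)) if asynchronies else np.nan
    return PinchResult(n_success, gap_time, asyn)


# ---------------------------------------------------------------------------
# Static Balance
# ---------------------------------------------------------------------------

def compute_sway_path(stream: SensorStream, duration: float = 30.0) -> float:
    """Postural sway during quiet standing, m/s².

    The gravity-removed horizontal acceleration trajectory is obtained by
    subtracting the per-stream mean from the two horizontal axes; sway path
    is the total path length traversed by that trajectory in acceleration
    space, Σ‖a(tᵢ₊₁) − a(tᵢ)‖.  Higher values indicate worse postural
    control.
    """
    if stream.modality != "inertial":
        raise ValueError("sway path requires an inertial stream")
    if len(stream) < 2:
        raise ValueError("need at least 2 samples")
    horiz = stream.accel[:, :2]
    horiz = horiz - horiz.mean(axis=0)
    return float(np.sum(np.linalg.norm(np.diff(horiz, axis=0), axis=1)))


# ---------------------------------------------------------------------------
# Two-Minute Walk
# ---------------------------------------------------------------------------

class WalkResult(NamedTuple):
    step_freq: float
    step_freq_var: float
    step_power: float


def _refine_peak(y: np.ndarray, t: np.ndarray, i: int) -> float:
    """Sub-sample peak time by quadratic interpolation around sample i."""
    if i <= 0 or i >= len(y) - 1:
        return float(t[i])
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(t[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    dt = (t[i + 1] - t[i - 1]) / 2
    return float(t[i] + np.clip(delta, -1, 1) * dt)


def compute_walk(stream: SensorStream, min_step_amplitude: float = 0.05,
                 max_cadence_hz: float = 4.0) -> WalkResult:
    """Gait measures from the vertical accelerometer axis of a walking test.

    The vertical (third) axis is detrended by removing its sub-0.5-Hz
    component (gravity and slow posture drift); step events are detected by
    peak-picking with quadratic sub-sample refinement.  Instantaneous step
    frequencies are the reciprocals of inter-step intervals; ``step_freq``
    and ``step_freq_var`` are their mean and variance.  ``step_power`` is
    the mean over steps of the time-integral of squared detrended
    acceleration within the step (m²/s³), a measure of gait intensity.

    Returns NaNs (stream effectively silent / no detectable steps)
    when fewer than 4 step peaks are found.
    """
    if stream.modality != "inertial":
        raise ValueError("walk measures require an inertial stream")
    t, az = stream.t, stream.accel[:, 2]
    if t[-1] - t[0] < 10.0:
        raise ValueError("walking stream shorter than 10 s")
    fs = (len(t) - 1) / (t[-1] - t[0])
    # remove <0.5 Hz component (gravity + drift)
    b, a = _sig.butter(2, 0.5 / (fs / 2), btype="low")
    det = az - _sig.filtfilt(b, a, az)
    height = max(min_step_amplitude, 0.3 * float(det.std()))
    dist = max(1, int(round(fs / max_cadence_hz)))
    peaks, _ = _sig.find_peaks(det, height=height, distance=dist)
    if len(peaks) < 4:
        return WalkResult(np.nan, np.nan, np.nan)
    pt = np.array([_refine_peak(det, t, i) for i in peaks])
    intervals = np.diff(pt)
    freqs = 1.0 / intervals
    step_freq = float(freqs.mean())
    step_freq_var = float(freqs.var(ddof=1))
    powers = []
    for k in range(len(peaks) - 1):
        sel = slice(peaks[k], peaks[k + 1] + 1)
        powers.append(np.trapezoid(det[sel] ** 2, t[sel]))
    return WalkResult(step_freq, step_freq_var, float(np.mean(powers)))


# ---------------------------------------------------------------------------
# U-Turn
# ---------------------------------------------------------------------------

def compute_turn_speed(stream: SensorStream, yaw_threshold: float = 0.3,
                       min_turn_angle: float = np.pi / 2) -> float:
    """Median turning speed over detected U-turns, rad/s.

    Turns are contiguous intervals where |yaw rate| exceeds
    ``yaw_threshold``; the turned angle is the time-integral of yaw rate
    over the interval and intervals turning less than ``min_turn_angle``
    are discarded.  Returns the median of angle/duration over the retained
    turns, or NaN when no turn is detected.
    """
    if stream.modality != "inertial" or stream.yaw_rate is None:
        raise ValueError("turn speed requires an inertial stream with yaw rate")
    t, yr = stream.t, stream.yaw_rate
    active = np.abs(yr) > yaw_threshold
    if not np.any(active):
        return np.nan
    edges = np.diff(active.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if active[0]:
        starts.insert(0, 0)
    if active[-1]:
        ends.append(len(active))
    speeds = []
    for s, e in zip(starts, ends):
        if e - s < 2:
            continue
        angle = abs(np.trapezoid(yr[s:e], t[s:e]))
        dur = t[e - 1] - t[s]
        if angle >= min_turn_angle and dur > 0:
            speeds.append(angle / dur)
    return float(np.median(speeds)) if speeds else np.nan


# ---------------------------------------------------------------------------
# Record-level extraction
# ---------------------------------------------------------------------------

def extract_record(record: TestRecord, per_shape: bool = False) -> dict[str, float]:
    """Compute all digital measures defined for one test administration.

    For the Draw a Shape Test the per-shape results are averaged over the
    shapes present (NaN-aware for angular/radial CVs, which exist only for
    round shapes); with ``per_shape=True`` additional ``<measure>__<shape>``
    entries are included alongside the shape-averaged ones.
    """
    tt = record.test_type
    out: dict[str, float] = {}
    if tt == "esdmt":
        r = compute_esdmt(record.responses if record.responses is not None
                          else np.zeros(0, dtype=[("t", float), ("correct", bool)]))
        out = {"esdmt_n_correct": float(r.n_correct),
               "esdmt_max_gap": r.max_gap, "esdmt_sfi30": r.sfi30}
    elif tt == "draw":
        per = {}
        for st in record.streams:
            shape = st.meta.get("shape")
            try:
                per[shape] = compute_draw_shape(st, shape)
            except ValueError:
                continue
        if per:
            arr = np.array([[p.accuracy, p.celerity, p.cv_linear,
                             p.cv_angular, p.cv_radial] for p in per.values()])
            with np.errstate(invalid="ignore"):
                means = np.nanmean(arr, axis=0)
        else:
            means = np.full(5, np.nan)
        out = dict(zip(["draw_accuracy", "draw_celerity", "draw_cv_linear",
                        "draw_cv_angular", "draw_cv_radial"], map(float, means)))
        if per_shape:
            for shape, p in per.items():
                out[f"draw_accuracy__{shape}"] = p.accuracy
                out[f"draw_cv_linear__{shape}"] = p.cv_linear
                if shape in _shapes.ROUND_SHAPES:
                    out[f"draw_cv_angular__{shape}"] = p.cv_angular
                    out[f"draw_cv_radial__{shape}"] = p.cv_radial
    elif tt == "pinch":
        r = compute_pinching(record.streams[0])
        out = {"pinch_n_success": float(r.n_success),
               "pinch_gap_time": r.gap_time, "pinch_asynchrony": r.asynchrony}
    elif tt == "sbt":
        out = {"sbt_sway_path": compute_sway_path(record.streams[0])}
    elif tt == "2mwt":
        r = compute_walk(record.streams[0])
        out = {"walk_step_freq": r.step_freq,
               "walk_step_freq_var": r.step_freq_var,
               "walk_step_power": r.step_power}
    elif tt == "utt":
        out = {"utt_turn_speed": compute_turn_speed(record.streams[0])}
    return out
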