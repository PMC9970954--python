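"""Synthetic cohort generator with a planted latent-disability structure.

Real raw data from the remote-monitoring study are not public, so every
downstream stage is exercised on a synthetic cohort in which the ground
truth is known.  A single latent disability factor drives both the regional
MRI outcomes and the sensor-level skill of each subject:

* region z-score:   ``z_r = λ_r·latent + covariate terms + √(1−λ_r²)·ε``,
  mapped to a volume ``μ_r + cv_r·μ_r·z_r`` (mL or mm²);
* measure driver:   ``z_m = λ_m·latent + covariate terms + √(1−λ_m²)·ε``,
  mapped monotonically onto the simulator parameter that controls the
  corresponding digital measure (drawing noise, pinch asynchrony, cadence,
  sway amplitude, ...).

Because the downstream correlation is rank-based, any monotone mapping
preserves the planted association: for Gaussian drivers the population
Spearman correlation between a measure and a region is approximately
``(6/π)·asin(λ_m·λ_r/2)``, attenuated slightly by extraction noise.

Covariates (age, sex, BMI) enter both sides, creating genuine confounding
that the adjusted correlation analysis must remove.  Demographics emulate
an early-MS cohort: 68% female, age 39.7 ± 7.5 (range 20–57) years,
BMI 24.4 ± 4.4 kg/m².  All randomness derives from the config seed; the
same config and seed reproduce bit-identical output.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig

from . import shapes as _shapes
from .features import CLINICAL_MEASURE_NAMES, DIGITAL_MEASURE_NAMES
from .regions import REGION_NAMES, REGIONS, TOTAL_BRAIN_VOLUME
from .streams import DOWN, MOVE, UP, SensorStream, TestRecord, TEST_TYPES, response_log

#: Sentinel skill for a noiseless, flawless performance.
PERFECT = -np.inf

_STUDY_START = _dt.datetime(2017, 1, 2)
_STUDY_DAYS = 168  # 24 weeks


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _default_region_loadings() -> dict[str, float]:
    return {r.name: r.loading for r in REGIONS}


def _default_measure_loadings() -> dict[str, float]:
    return {m: 0.55 for m in DIGITAL_MEASURE_NAMES}


def _default_covariate_effects() -> dict[str, dict[str, float]]:
    # slopes on the standardized z-scale per unit of centered covariate;
    # age enters both sides (atrophy and slower performance) -> confounding
    return {
        "age": {"region": -0.030, "measure": 0.025},
        "sex": {"region": 0.10, "measure": -0.05},   # M=1
        "bmi": {"region": -0.010, "measure": 0.010},
    }


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_subjects: int = 62
    seed: int = 0
    latent_sd: float = 1.0
    loading_map: dict[str, float] = field(default_factory=_default_region_loadings)
    measure_loading_map: dict[str, float] = field(default_factory=_default_measure_loadings)
    noise_sd_region: float = 0.01     # scan-level measurement noise, fraction of mean
    covariate_effects: dict[str, dict[str, float]] = field(
        default_factory=_default_covariate_effects)
    sampling_rate_inertial: float = 50.0
    tests_per_subject: int = 7        # administrations per test type over 24 weeks
    age_range: tuple[float, float] = (18.0, 57.0)
    n_low_adherence: int = 0          # subjects contributing too few tests
    n_missing_mri: int = 0            # subjects without MRI scans
    low_adherence_tests: int = 2      # administrations per type for those subjects
    walk_duration: float = 120.0
    utt_duration: float = 45.0
    sbt_duration: float = 30.0

    def __post_init__(self):
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if self.sampling_rate_inertial <= 0:
            raise ValueError("sampling_rate_inertial must be > 0")
        for name in self.loading_map:
            if name not in REGION_NAMES and name != TOTAL_BRAIN_VOLUME:
                raise ValueError(f"invalid loading for unknown region name {name!r}")
        for name in self.measure_loading_map:
            if name not in DIGITAL_MEASURE_NAMES:
                raise ValueError(f"invalid loading for unknown measure {name!r}")
        if self.n_low_adherence + self.n_missing_mri > self.n_subjects:
            raise ValueError("excluded subject groups exceed cohort size")


@dataclass
class SubjectProfile:
    subject_id: str
    age: float
    sex: str                  # "F" | "M"
    bmi: float
    latent_disability: float  # dimensionless z-score
    site: str


@dataclass
class SyntheticCohort:
    """Everything `simulate_cohort` produces, with ground truth attached."""

    config: CohortConfig
    subjects: list[SubjectProfile]
    covariates: pd.DataFrame          # subject_id × (age, sex, bmi); sex F=0/M=1
    region_scans: pd.DataFrame        # long: subject_id, scan, 36 regions + TBV
    region_table: pd.DataFrame        # subject-level mean over scans
    clinical_visits: pd.DataFrame     # long: subject_id, visit, 5 clinical scores
    clinical_table: pd.DataFrame      # subject-level mean over visits
    records: list[TestRecord]
    truth: dict                       # latent, measure drivers, region z-scores


# ---------------------------------------------------------------------------
# Stream simulators
# ---------------------------------------------------------------------------

def _smooth_noise(rng, n: int, fs: float, sd: float, cutoff_hz: float = 3.0) -> np.ndarray:
    """Low-pass-filtered Gaussian noise with the requested pointwise SD."""
    if sd == 0 or n < 15:
        return np.zeros(n)
    w = rng.standard_normal(n)
    b, a = _sig.butter(2, min(cutoff_hz / (fs / 2), 0.99), btype="low")
    f = _sig.filtfilt(b, a, w)
    s = f.std()
    return f * (sd / s) if s > 0 else np.zeros(n)


_DRAW_BASE_DURATION = {"line1": 1.2, "line2": 1.2, "square": 2.5,
                       "circle": 2.2, "figure8": 3.0, "spiral": 4.0}


def simulate_draw_shape_stream(skill: float, shape: str, seed, *,
                               pos_noise: float | None = None,
                               speed_jitter: float | None = None,
                               duration: float | None = None,
                               fs: float = 60.0) -> SensorStream:
    """Simulate one drawn shape as a touch stream.

    ``skill`` is a disability z-score (0 = typical, larger = worse,
    :data:`PERFECT` = flawless).  The trace follows the reference polyline
    with smooth positional noise (SD ``pos_noise`` px, default
    ``6·exp(0.5·skill)``) and multiplicative per-segment speed jitter
    (lognormal sigma ``speed_jitter``, default ``0.08·exp(0.4·skill)``).
    Timestamps are strictly increasing.
    """
    if shape not in _shapes.SHAPE_IDS:
        raise ValueError(f"unknown shape id {shape!r}")
    rng = _rng(seed)
    if pos_noise is None:
        pos_noise = 6.0 * math.exp(0.5 * skill)
    if speed_jitter is None:
        speed_jitter = 0.08 * math.exp(0.4 * skill)
    if duration is None:
        duration = _DRAW_BASE_DURATION[shape] * math.exp(0.15 * max(skill, 0.0))
    n = max(int(round(duration * fs)) + 1, 8)
    pts = _shapes.resample_arclength(shape, n)
    if pos_noise > 0:
        pts = pts + np.column_stack([_smooth_noise(rng, n, fs, pos_noise),
                                     _smooth_noise(rng, n, fs, pos_noise)])
    dt = np.full(n - 1, duration / (n - 1))
    if speed_jitter > 0:
        dt = dt * np.exp(rng.normal(0.0, speed_jitter, n - 1))
    t = np.concatenate([[0.0], np.cumsum(dt)])
    phase = np.full(n, MOVE)
    phase[0], phase[-1] = DOWN, UP
    return SensorStream.touch(t, pts[:, 0], pts[:, 1], np.zeros(n, int),
                              phase, meta={"shape": shape})


def simulate_pinch_stream(skill: float, seed, *, duration: float = 30.0,
                          gap_mean: float | None = None,
                          asynchrony_mean: float | None = None,
                          success_prob: float | None = None,
                          fixed_asynchrony: float | None = None) -> SensorStream:
    """Simulate one 30-s pinching test as a two-pointer touch stream.

    Gestures are scheduled sequentially; each has an inter-finger contact
    asynchrony (exponential with mean ``asynchrony_mean``, or the constant
    ``fixed_asynchrony``), a gamma-distributed gap to the next attempt, and
    succeeds with ``success_prob`` (failures land one pointer off-target).
    The planted per-gesture values are stored in ``meta['planted']`` so
    tests can compare extraction against the generator log exactly.
    """
    if duration <= 0:
        raise ValueError("non-positive duration")
    rng = _rng(seed)
    if gap_mean is None:
        gap_mean = 0.7 * math.exp(0.30 * skill)
    if asynchrony_mean is None:
        asynchrony_mean = 0.08 * math.exp(0.35 * skill)
    if success_prob is None:
        success_prob = float(np.clip(0.95 - 0.10 * max(skill, 0.0), 0.05, 1.0))

    gesture_dur = 0.4
    targets, planted_asyn, planted_gap, success_flags = [], [], [], []
    ev = {"t": [], "x": [], "y": [], "pid": [], "ph": []}
    t0 = 0.5
    while t0 + gesture_dur < duration:
        cx, cy = rng.uniform(100, 500, 2)
        r_tg = 50.0
        targets.append({"t_appear": t0 - 0.2, "x": cx, "y": cy, "r": r_tg})
        asyn = (fixed_asynchrony if fixed_asynchrony is not None
                else rng.exponential(asynchrony_mean))
        asyn = min(asyn, gesture_dur * 0.8)
        ok = rng.random() < success_prob
        planted_asyn.append(asyn)
        success_flags.append(ok)
        # pointer start/end positions: converge toward the target centre
        angle = rng.uniform(0, 2 * np.pi)
        u = np.array([np.cos(angle), np.sin(angle)])
        start_a, start_b = np.array([cx, cy]) + 40 * u, np.array([cx, cy]) - 40 * u
        if not ok:  # miss: first pointer lands outside the target
            start_a = np.array([cx, cy]) + (r_tg + 40) * u
        end_a = np.array([cx, cy]) + 12 * u
        end_b = np.array([cx, cy]) - 12 * u
        for pid, (p0, p1, td) in enumerate(
                [(start_a, end_a, t0), (start_b, end_b, t0 + asyn)]):
            n_mv = 8
            ts = np.linspace(td, t0 + gesture_dur, n_mv)
            frac = np.linspace(0, 1, n_mv)[:, None]
            xy = p0 + (p1 - p0) * frac
            phases = [DOWN] + [MOVE] * (n_mv - 2) + [UP]
            for k in range(n_mv):
                ev["t"].append(ts[k]); ev["x"].append(xy[k, 0])
                ev["y"].append(xy[k, 1]); ev["pid"].append(pid)
                ev["ph"].append(phases[k])
        gap = rng.gamma(4.0, gap_mean / 4.0)
        planted_gap.append(gap)
        t0 += gesture_dur + gap

    order = np.argsort(np.array(ev["t"]), kind="stable")
    meta = {"targets": targets,
            "planted": {"asynchronies": planted_asyn, "gaps": planted_gap[:-1],
                        "success": success_flags}}
    return SensorStream.touch(np.array(ev["t"])[order], np.array(ev["x"])[order],
                              np.array(ev["y"])[order],
                              np.array(ev["pid"])[order],
                              np.array(ev["ph"])[order], meta=meta)


def simulate_esdmt_responses(skill: float, seed, *, duration: float = 90.0,
                             rate: float | None = None,
                             fatigue: float | None = None,
                             burstiness: float | None = None) -> np.ndarray:
    """Simulate an e-SDMT response log (timestamps + correctness).

    Correct responses follow a gamma-renewal process with base rate
    ``rate`` (correct/s, default ``0.35·exp(−0.25·skill)``) thinned by
    ``fatigue`` in the final 30 s; lower ``burstiness`` shape values give
    burstier responding and larger maximum gaps.  A small uniform rate of
    incorrect responses is superimposed.
    """
    rng = _rng(seed)
    if rate is None:
        rate = 0.35 * math.exp(-0.25 * skill)
    if fatigue is None:
        fatigue = float(np.clip(math.exp(-0.15 * skill), 0.3, 1.1))
    if burstiness is None:
        burstiness = 2.0 * math.exp(-0.30 * skill)
    times = []
    t = 0.0
    while True:
        r_now = rate * (fatigue if t > duration - 30.0 else 1.0)
        if r_now <= 0:
            break
        t += rng.gamma(burstiness, 1.0 / (burstiness * r_now))
        if t >= duration:
            break
        times.append(t)
    n_wrong = rng.poisson(0.02 * duration)
    wrong = rng.uniform(0, duration, n_wrong)
    return response_log(np.concatenate([times, wrong]),
                        [True] * len(times) + [False] * n_wrong)


def simulate_inertial_stream(kind: str, seed, *, fs: float = 50.0,
                             duration: float | None = None,
                             f0: float = 1.85, a0: float = 2.0,
                             freq_jitter: float = 0.0,
                             noise: float = 0.05,
                             sway_amp: float = 0.12,
                             turn_duration: float = 2.0,
                             n_turns: int = 5,
                             freq_fn=None) -> SensorStream:
    """Simulate an accelerometer (+ yaw-rate) stream for a gait/balance test.

    kind='balance'
        Low-amplitude noise around gravity; ``sway_amp`` scales the
        horizontal noise SD (m/s²), 0 gives a perfectly still device.
    kind='walk'
        Cadence-locked vertical oscillation at step frequency ``f0`` Hz,
        amplitude ``a0`` m/s², with optional slow cadence wander of SD
        ``freq_jitter`` Hz (or an explicit ``freq_fn(t)->Hz``).
    kind='uturn'
        A walking stream with ``n_turns`` raised-cosine yaw-rate bursts of
        alternating sign, each integrating to π rad over ``turn_duration`` s.
    """
    if fs <= 0:
        raise ValueError("non-positive sampling rate")
    if duration is None:
        duration = {"balance": 30.0, "walk": 120.0, "uturn": 45.0}[kind]
    if duration <= 0:
        raise ValueError("non-positive duration")
    rng = _rng(seed)
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs

    if kind == "balance":
        ax = _smooth_noise(rng, n, fs, sway_amp, cutoff_hz=4.0)
        ay = _smooth_noise(rng, n, fs, sway_amp, cutoff_hz=4.0)
        az = 9.81 + _smooth_noise(rng, n, fs, 0.3 * sway_amp, cutoff_hz=4.0)
        return SensorStream.inertial(t, np.column_stack([ax, ay, az]))

    if kind not in ("walk", "uturn"):
        raise ValueError(f"unknown inertial test kind {kind!r}")

    if freq_fn is not None:
        f_inst = np.asarray([freq_fn(tk) for tk in t], float)
    else:
        f_inst = np.full(n, f0)
        if freq_jitter > 0:
            f_inst = f_inst + _smooth_noise(rng, n, fs, freq_jitter, cutoff_hz=0.3)
    phase = 2 * np.pi * np.concatenate([[0.0], np.cumsum(f_inst[:-1]) / fs])
    az = 9.81 + a0 * np.sin(phase)
    if noise > 0:
        az = az + rng.normal(0, noise, n)
    ax = rng.normal(0, noise, n) if noise > 0 else np.zeros(n)
    ay = rng.normal(0, noise, n) if noise > 0 else np.zeros(n)
    accel = np.column_stack([ax, ay, az])

    if kind == "walk":
        return SensorStream.inertial(t, accel)

    yaw = rng.normal(0, 0.02, n) if noise > 0 else np.zeros(n)
    margin = 3.0
    centers = np.linspace(margin + turn_duration / 2,
                          duration - margin - turn_duration / 2, n_turns)
    amp = 2 * np.pi / turn_duration  # raised cosine integrating to pi
    for k, c in enumerate(centers):
        sel = np.abs(t - c) <= turn_duration / 2
        tau = (t[sel] - (c - turn_duration / 2)) / turn_duration
        yaw[sel] += ((-1) ** k) * (amp / 2) * (1 - np.cos(2 * np.pi * tau))
    return SensorStream.inertial(t, accel, yaw_rate=yaw)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

_CLINICAL_LOADINGS = {"edss": 0.80, "oral_sdmt": 0.60, "hpt9": 0.60,
                      "t25fw": 0.60, "berg_balance": 0.60}


def _driver(rng, latent, loading, cov_term):
    lam = float(np.clip(loading, -1.0, 1.0))
    resid = math.sqrt(max(0.0, 1.0 - lam * lam))
    return lam * latent + cov_term + resid * rng.standard_normal(len(latent))


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort under ``config``.

    Produces subject profiles, scan-level regional MRI tables (two scans),
    visit-level clinical scores (three visits), and one
    :class:`~digibrain.streams.TestRecord` per administration of each of
    the six active tests.  The last ``n_low_adherence`` subjects contribute
    only ``low_adherence_tests`` administrations per test type, and the
    ``n_missing_mri`` subjects before them have no MRI scans, so the
    quality-control stage has realistic exclusions to perform.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5EED]))
    n = cfg.n_subjects
    ids = [f"S{i + 1:03d}" for i in range(n)]
    latent = rng.normal(0.0, cfg.latent_sd, n)

    lo, hi = cfg.age_range
    age = np.clip(rng.normal(39.7, 7.5, n), max(lo, 20.0), hi)
    sex = (rng.random(n) > 0.677).astype(int)          # M=1, ~32%
    bmi = np.clip(rng.normal(24.4, 4.4, n), 17.1, 37.6)
    site = np.where(rng.random(n) < 11 / 62, "USA", "Spain")
    age_c, bmi_c = age - 39.7, bmi - 24.4

    eff = cfg.covariate_effects

    def cov_term(kind):
        out = np.zeros(n)
        for cname, vals in (("age", age_c), ("sex", sex), ("bmi", bmi_c)):
            out = out + eff.get(cname, {}).get(kind, 0.0) * vals
        return out

    cov_region = cov_term("region")
    cov_measure = cov_term("measure")

    subjects = [SubjectProfile(ids[i], float(age[i]), "M" if sex[i] else "F",
                               float(bmi[i]), float(latent[i]), str(site[i]))
                for i in range(n)]
    covariates = pd.DataFrame({"age": age, "sex": sex, "bmi": bmi}, index=ids)
    covariates.index.name = "subject_id"

    # --- regional MRI, two scans ------------------------------------
    region_z = {}
    scan_rows = []
    true_vol = {}
    for r in REGIONS:
        name, mu, cv = r.name, r.mean, r.cv
        lam = cfg.loading_map.get(name, r.loading)
        z = _driver(rng, latent, lam, cov_region)
        region_z[name] = z
        true_vol[name] = np.maximum(mu + cv * mu * z, 0.1 * mu)
    # total brain volume is (to measurement error) the sum of the regional
    # volumes; rescale the roster total to the population mean of 1471.9 mL
    ml_sum = sum(true_vol[r.name] for r in REGIONS if r.unit == "mL")
    ml_mean = sum(r.mean for r in REGIONS if r.unit == "mL")
    true_vol[TOTAL_BRAIN_VOLUME] = ml_sum * (1471.9 / ml_mean)
    region_z[TOTAL_BRAIN_VOLUME] = (ml_sum - ml_mean) / np.std(ml_sum)
    mri_ids = ids[:n - cfg.n_low_adherence - cfg.n_missing_mri] + \
        ids[n - cfg.n_low_adherence:]
    for scan in ("baseline", "week24"):
        for i, sid in enumerate(ids):
            if sid not in mri_ids:
                continue
            row = {"subject_id": sid, "scan": scan}
            for name, tv in true_vol.items():
                noise = rng.normal(0.0, cfg.noise_sd_region * tv[i])
                row[name] = max(tv[i] + noise, 0.01)
            scan_rows.append(row)
    region_scans = pd.DataFrame(scan_rows)
    region_table = (region_scans.drop(columns="scan")
                    .groupby("subject_id").mean()
                    .reindex([s for s in ids if s in mri_ids]))

    # --- clinical scores, three visits ------------------------------
    zc = {m: _driver(rng, latent, _CLINICAL_LOADINGS[m], cov_measure)
          for m in CLINICAL_MEASURE_NAMES}
    visit_rows = []
    for visit in ("baseline", "week12", "week24"):
        for i, sid in enumerate(ids):
            edss = np.clip(2.5 + 1.3 * zc["edss"][i] + rng.normal(0, 0.25), 0.0, 6.5)
            visit_rows.append({
                "subject_id": sid, "visit": visit,
                "edss": round(edss * 2) / 2,
                "oral_sdmt": max(0.0, round(53.4 - 9.0 * zc["oral_sdmt"][i]
                                            + rng.normal(0, 2.0))),
                "hpt9": 22.4 * math.exp(0.15 * zc["hpt9"][i] + rng.normal(0, 0.03)),
                "t25fw": 6.0 * math.exp(0.25 * zc["t25fw"][i] + rng.normal(0, 0.04)),
                "berg_balance": float(np.clip(round(52.4 - 4.5 * zc["berg_balance"][i]
                                                    + rng.normal(0, 1.0)), 0, 56)),
            })
    clinical_visits = pd.DataFrame(visit_rows)
    clinical_table = (clinical_visits.drop(columns="visit")
                      .groupby("subject_id").mean().reindex(ids))

    # --- per-measure drivers and sensor streams ---------------------
    zm = pd.DataFrame(
        {m: _driver(rng, latent, cfg.measure_loading_map.get(m, 0.55), cov_measure)
         for m in DIGITAL_MEASURE_NAMES}, index=ids)

    records: list[TestRecord] = []
    fs = cfg.sampling_rate_inertial
    for i, sid in enumerate(ids):
        is_low = i >= n - cfg.n_low_adherence
        n_tests = cfg.low_adherence_tests if is_low else cfg.tests_per_subject
        if n_tests > 1:
            days = np.linspace(0, _STUDY_DAYS, n_tests)
        else:
            days = np.array([0.0])
        z = zm.loc[sid]
        for ti, tt in enumerate(TEST_TYPES):
            for k in range(n_tests):
                seed_k = np.random.SeedSequence([cfg.seed, 7919, i, ti, k])
                srng = np.random.default_rng(seed_k)
                start = _STUDY_START + _dt.timedelta(days=float(days[k]),
                                                     hours=9 + ti)
                rec = TestRecord(sid, tt, start)
                if tt == "esdmt":
                    rec.responses = simulate_esdmt_responses(
                        0.0, srng,
                        rate=0.35 * math.exp(-0.25 * z["esdmt_n_correct"]),
                        fatigue=float(np.clip(math.exp(-0.15 * z["esdmt_sfi30"]),
                                              0.3, 1.1)),
                        burstiness=2.0 * math.exp(-0.30 * z["esdmt_max_gap"]))
                elif tt == "draw":
                    for shape in _shapes.SHAPE_IDS:
                        rec.streams.append(simulate_draw_shape_stream(
                            0.0, shape, srng,
                            pos_noise=6.0 * math.exp(0.5 * z["draw_accuracy"]),
                            speed_jitter=0.08 * math.exp(0.4 * z["draw_cv_linear"]),
                            duration=_DRAW_BASE_DURATION[shape]
                            * math.exp(0.15 * max(z["draw_celerity"], 0.0))))
                elif tt == "pinch":
                    rec.streams.append(simulate_pinch_stream(
                        0.0, srng,
                        gap_mean=0.7 * math.exp(0.30 * z["pinch_gap_time"]),
                        asynchrony_mean=0.08 * math.exp(0.35 * z["pinch_asynchrony"]),
                        success_prob=float(np.clip(
                            0.95 - 0.10 * max(z["pinch_n_success"], 0.0), 0.05, 1.0))))
                elif tt == "sbt":
                    rec.streams.append(simulate_inertial_stream(
                        "balance", srng, fs=fs, duration=cfg.sbt_duration,
                        sway_amp=0.12 * math.exp(0.4 * z["sbt_sway_path"])))
                elif tt == "2mwt":
                    rec.streams.append(simulate_inertial_stream(
                        "walk", srng, fs=fs, duration=cfg.walk_duration,
                        f0=float(np.clip(1.85 - 0.12 * z["walk_step_freq"], 0.8, 3.0)),
                        a0=2.0 * math.exp(-0.25 * z["walk_step_power"]),
                        freq_jitter=0.04 * math.exp(0.4 * z["walk_step_freq_var"])))
                elif tt == "utt":
                    rec.streams.append(simulate_inertial_stream(
                        "uturn", srng, fs=fs, duration=cfg.utt_duration,
                        turn_duration=float(np.clip(
                            1.8 * math.exp(0.30 * z["utt_turn_speed"]), 0.8, 6.0))))
                records.append(rec)

    truth = {"latent": pd.Series(latent, index=ids, name="latent"),
             "measure_drivers": zm,
             "region_z": pd.DataFrame(region_z, index=ids)}
    return SyntheticCohort(cfg, subjects, covariates, region_scans, region_table,
                           clinical_visits, clinical_table, records, truth)
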