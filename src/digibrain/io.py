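"""Readers and writers for sensor streams and analysis tables.

Streams are serialized as line-delimited JSON (a header line with the
modality and metadata, then one event per line) or as long-format CSV
(t, field, value).  Tables travel as CSV with a sidecar JSON schema file
recording units and direction-of-better per column.  A simulated cohort is
written to a directory with a record manifest so that each pipeline stage
can be run separately on files.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import MEASURE_INFO
from .regions import REGION_NAMES, REGION_UNITS, TOTAL_BRAIN_VOLUME
from .streams import PHASE_CODES, PHASE_NAMES, SensorStream, TestRecord

_TIME_FMT = "%Y-%m-%dT%H:%M:%S"


# ---------------------------------------------------------------------------
# Streams
# ---------------------------------------------------------------------------

def write_stream_jsonl(stream: SensorStream, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        header = {"type": "header", "modality": stream.modality,
                  "meta": _jsonable(stream.meta)}
        fh.write(json.dumps(header) + "\n")
        for i in range(len(stream)):
            ev: dict = {"t": float(stream.t[i]), "modality": stream.modality}
            if stream.modality == "touch":
                ev.update(x=float(stream.x[i]), y=float(stream.y[i]),
                          pointer_id=int(stream.pointer_id[i]),
                          phase=PHASE_NAMES[int(stream.phase[i])])
            else:
                ev.update(ax=float(stream.accel[i, 0]),
                          ay=float(stream.accel[i, 1]),
                          az=float(stream.accel[i, 2]))
                if stream.yaw_rate is not None:
                    ev["yaw_rate"] = float(stream.yaw_rate[i])
            fh.write(json.dumps(ev) + "\n")


def read_stream_jsonl(path) -> SensorStream:
    path = Path(path)
    events = []
    header = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from exc
            if obj.get("type") == "header":
                header = obj
            else:
                events.append(obj)
    if header is None:
        raise ValueError(f"{path}: missing stream header line")
    modality = header["modality"]
    meta = header.get("meta", {})
    t = np.array([e["t"] for e in events])
    if modality == "touch":
        return SensorStream.touch(
            t, [e["x"] for e in events], [e["y"] for e in events],
            [e["pointer_id"] for e in events],
            [PHASE_CODES[e["phase"]] for e in events], meta=meta)
    accel = np.column_stack([[e["ax"] for e in events],
                             [e["ay"] for e in events],
                             [e["az"] for e in events]])
    yaw = None
    if events and "yaw_rate" in events[0]:
        yaw = np.array([e["yaw_rate"] for e in events])
    return SensorStream.inertial(t, accel, yaw_rate=yaw, meta=meta)


def write_stream_csv(stream: SensorStream, path) -> None:
    """Long-format CSV (t, field, value); metadata goes in a JSON sidecar."""
    rows = []
    for i in range(len(stream)):
        t = float(stream.t[i])
        if stream.modality == "touch":
            fields = {"x": stream.x[i], "y": stream.y[i],
                      "pointer_id": stream.pointer_id[i],
                      "phase": stream.phase[i]}
        else:
            fields = {"ax": stream.accel[i, 0], "ay": stream.accel[i, 1],
                      "az": stream.accel[i, 2]}
            if stream.yaw_rate is not None:
                fields["yaw_rate"] = stream.yaw_rate[i]
        for k, v in fields.items():
            rows.append((t, k, float(v)))
    pd.DataFrame(rows, columns=["t", "field", "value"]).to_csv(path, index=False)
    Path(str(path) + ".meta.json").write_text(json.dumps(
        {"modality": stream.modality, "meta": _jsonable(stream.meta)}))


def read_stream_csv(path) -> SensorStream:
    df = pd.read_csv(path)
    info = json.loads(Path(str(path) + ".meta.json").read_text())
    wide = df.pivot_table(index="t", columns="field", values="value",
                          aggfunc="first").reset_index().sort_values("t")
    if info["modality"] == "touch":
        return SensorStream.touch(wide["t"], wide["x"], wide["y"],
                                  wide["pointer_id"].astype(int),
                                  wide["phase"].astype(int), meta=info["meta"])
    accel = wide[["ax", "ay", "az"]].to_numpy()
    yaw = wide["yaw_rate"].to_numpy() if "yaw_rate" in wide else None
    return SensorStream.inertial(wide["t"], accel, yaw_rate=yaw, meta=info["meta"])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# Tables with schema sidecars
# ---------------------------------------------------------------------------

def _schema_path(path) -> Path:
    return Path(str(path) + ".schema.json")


def measure_schema(columns) -> dict:
    sch = {}
    for c in columns:
        info = MEASURE_INFO.get(str(c))
        sch[str(c)] = ({"unit": info.unit, "higher_is_better": info.higher_is_better}
                       if info else {"unit": "", "higher_is_better": None})
    return sch


def region_schema(columns) -> dict:
    sch = {}
    for c in columns:
        unit = REGION_UNITS.get(str(c), "mL" if c == TOTAL_BRAIN_VOLUME else "")
        sch[str(c)] = {"unit": unit, "higher_is_better": None}
    return sch


def write_table_csv(df: pd.DataFrame, path, schema: dict | None = None) -> None:
    """Write a subject-indexed table with a JSON schema sidecar."""
    df.to_csv(path, index_label=df.index.name or "subject_id")
    if schema is not None:
        _schema_path(path).write_text(json.dumps({"columns": schema}, indent=1))


def read_table_csv(path) -> tuple[pd.DataFrame, dict | None]:
    df = pd.read_csv(path, index_col=0)
    sp = _schema_path(path)
    schema = json.loads(sp.read_text())["columns"] if sp.exists() else None
    return df, schema


def read_region_table(path) -> pd.DataFrame:
    """Read a regional MRI table, checking the roster and units."""
    df, schema = read_table_csv(path)
    missing = [c for c in REGION_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"region table lacks columns: {missing}")
    if schema:
        for name, expected in REGION_UNITS.items():
            got = schema.get(name, {}).get("unit")
            if got is not None and got != expected:
                raise ValueError(
                    f"unit mismatch for region {name!r}: {got!r} != {expected!r}")
    return df


# ---------------------------------------------------------------------------
# Cohort directory layout
# ---------------------------------------------------------------------------

def write_cohort(cohort, out_dir, stream_format: str = "jsonl") -> None:
    """Serialize a simulated cohort to ``out_dir`` (streams + tables + manifest)."""
    out = Path(out_dir)
    (out / "streams").mkdir(parents=True, exist_ok=True)
    write_table_csv(cohort.covariates, out / "covariates.csv")
    cohort.region_scans.to_csv(out / "region_scans.csv", index=False)
    cohort.clinical_visits.to_csv(out / "clinical_visits.csv", index=False)
    write_table_csv(cohort.region_table, out / "region_table.csv",
                    region_schema(cohort.region_table.columns))

    writer = write_stream_jsonl if stream_format == "jsonl" else write_stream_csv
    ext = "jsonl" if stream_format == "jsonl" else "csv"
    rows = []
    for rid, rec in enumerate(cohort.records):
        files = []
        for k, st in enumerate(rec.streams):
            rel = f"streams/r{rid:05d}_{k}.{ext}"
            writer(st, out / rel)
            files.append(rel)
        if rec.responses is not None:
            rel = f"streams/r{rid:05d}_responses.csv"
            pd.DataFrame({"t": rec.responses["t"],
                          "correct": rec.responses["correct"].astype(int)}
                         ).to_csv(out / rel, index=False)
            files.append(rel)
        rows.append({"record_id": rid, "subject_id": rec.subject_id,
                     "test_type": rec.test_type,
                     "start_time": rec.start_time.strftime(_TIME_FMT),
                     "files": ";".join(files)})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)


def read_cohort_records(in_dir) -> list[TestRecord]:
    """Rebuild test records from a cohort directory's manifest."""
    from .streams import response_log
    root = Path(in_dir)
    manifest = pd.read_csv(root / "manifest.csv")
    records = []
    for _, row in manifest.iterrows():
        rec = TestRecord(str(row["subject_id"]), str(row["test_type"]),
                         _dt.datetime.strptime(row["start_time"], _TIME_FMT))
        for rel in str(row["files"]).split(";"):
            if not rel:
                continue
            p = root / rel
            if rel.endswith("_responses.csv"):
                df = pd.read_csv(p)
                rec.responses = response_log(df["t"], df["correct"].astype(bool))
            elif rel.endswith(".jsonl"):
                rec.streams.append(read_stream_jsonl(p))
            else:
                rec.streams.append(read_stream_csv(p))
        records.append(rec)
    return records
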