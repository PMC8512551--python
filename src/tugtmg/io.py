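"""CSV/JSON readers and writers for recordings, manifests and result tables.

CSV dialect: UTF-8, header row, '.' decimal separator, LF or CRLF line
endings.  Distance signals use columns ``time_s, distance_m``; twitch traces
use ``time_ms, displacement_mm``.  Participants are linked to their recording
files through a JSON manifest rather than filename conventions.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tmg import TMGResponse
from .tug import DistanceSignal

__all__ = [
    "ParseError",
    "read_distance_csv",
    "write_distance_csv",
    "read_tmg_csv",
    "write_tmg_csv",
    "read_manifest",
    "write_manifest",
    "write_cohort",
    "load_yaml",
]

#: significant digits preserved by the CSV writers (round-trip to 1e-6)
_FLOAT_FORMAT = "%.9g"


class ParseError(ValueError):
    """A malformed input file, with offending line numbers where known."""


def _read_numeric_csv(path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as err:
        raise ParseError(f"{path}: cannot parse CSV ({err})") from err
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {', '.join(missing)}")
    out = {}
    for col in required:
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            # +2: header row plus 1-based numbering
            lines = ", ".join(str(i + 2) for i in bad[bad].index[:10])
            raise ParseError(f"{path}: non-numeric values in column {col!r} at line(s) {lines}")
        out[col] = num.to_numpy(dtype=float)
    return pd.DataFrame(out)


def read_distance_csv(path, meta: dict | None = None) -> DistanceSignal:
    """Read one TUG recording from a ``time_s, distance_m`` CSV."""
    df = _read_numeric_csv(path, ("time_s", "distance_m"))
    m = dict(meta or {})
    m.setdefault("source", str(path))
    return DistanceSignal(time_s=df["time_s"].to_numpy(), distance_m=df["distance_m"].to_numpy(), meta=m)


def write_distance_csv(signal: DistanceSignal, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": signal.time_s, "distance_m": signal.distance_m}).to_csv(
        path, index=False, float_format=_FLOAT_FORMAT
    )
    return path


def read_tmg_csv(path, muscle: str = "", meta: dict | None = None) -> TMGResponse:
    """Read one twitch trace from a ``time_ms, displacement_mm`` CSV."""
    df = _read_numeric_csv(path, ("time_ms", "displacement_mm"))
    m = dict(meta or {})
    m.setdefault("source", str(path))
    return TMGResponse(
        time_ms=df["time_ms"].to_numpy(),
        displacement_mm=df["displacement_mm"].to_numpy(),
        muscle=muscle,
        meta=m,
    )


def write_tmg_csv(response: TMGResponse, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"time_ms": response.time_ms, "displacement_mm": response.displacement_mm}
    ).to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    return path


def read_manifest(path) -> dict:
    """Read the participant -> recording-files manifest.

    Structure::

        {"participants": {
            "P01": {"tug": ["tug/P01_t00.csv", ...],
                    "tmg": {"VM": ["tmg/P01_VM_r0.csv", ...], ...}},
            ...}}

    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if "participants" not in data:
        raise ParseError(f"{path}: manifest missing 'participants' key")
    base = path.parent
    for pid, entry in data["participants"].items():
        entry["tug"] = [str((base / p)) for p in entry.get("tug", [])]
        entry["tmg"] = {
            m: [str((base / p)) for p in files] for m, files in entry.get("tmg", {}).items()
        }
    return data


def write_manifest(manifest: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def write_cohort(cohort, outdir) -> dict:
    """Write a synthetic cohort as raw CSV recordings + manifest + ground truth.

    Layout: ``tug/<pid>_t<k>.csv``, ``tmg/<pid>_<muscle>_r<k>.csv``,
    ``manifest.json`` and ``ground_truth.json`` under ``outdir``.  Returns the
    manifest dict (with paths relative to ``outdir``).
    """
    outdir = Path(outdir)
    participants: dict = {}
    for item in cohort.tug_recordings:
        pid, k = item["participant_id"], item["test_index"]
        rel = f"tug/{pid}_t{k:02d}.csv"
        write_distance_csv(item["recording"].signal, outdir / rel)
        participants.setdefault(pid, {"tug": [], "tmg": {}})["tug"].append(rel)
    for item in cohort.tmg_recordings:
        pid, m, rep = item["participant_id"], item["muscle"], item["replicate"]
        rel = f"tmg/{pid}_{m}_r{rep}.csv"
        write_tmg_csv(item["recording"].response, outdir / rel)
        participants.setdefault(pid, {"tug": [], "tmg": {}})["tmg"].setdefault(m, []).append(rel)
    manifest = {"participants": participants}
    write_manifest(manifest, outdir / "manifest.json")

    truth = {
        "tug_participant_truth": cohort.truth_tug.to_dict(orient="records"),
        "tmg_participant_truth": cohort.truth_tmg.to_dict(orient="records"),
        "per_test_boundaries": [
            {
                "participant_id": item["participant_id"],
                "test_index": item["test_index"],
                **item["recording"].truth,
            }
            for item in cohort.tug_recordings
        ],
    }
    with open(outdir / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def load_yaml(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}
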