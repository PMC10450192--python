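"""Trace/manifest file formats and results serialisation.

Traces are UTF-8 tab-separated files with columns time_s, force_pN,
extension_nm (any column order; addressed by name; '.gz' paths are handled
transparently). Ensembles carry a JSON manifest listing every trace with
its kind and the full generator or acquisition parameters.
"""

from __future__ import annotations

import dataclasses
import gzip
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import Trace

REQUIRED_COLUMNS = ("time_s", "force_pN", "extension_nm")


class TraceParseError(ValueError):
    """Malformed trace file; message names the file, line and offense."""


def read_trace(path, event_id: str | None = None, kind: str = "ejection") -> Trace:
    """Read one trace TSV, validating columns, numeric cells and time order."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TraceParseError(f"{path}: missing columns {missing}")
    df = df[list(REQUIRED_COLUMNS)]
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna().any(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise TraceParseError(f"{path}: non-numeric cell at line {line}")
    t = coerced["time_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        line = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 3
        raise TraceParseError(f"{path}: non-increasing time_s at line {line}")
    return Trace(
        event_id=event_id or path.stem.removesuffix(".tsv"),
        kind=kind,
        time=t,
        force=coerced["force_pN"].to_numpy(float),
        extension=coerced["extension_nm"].to_numpy(float),
        metadata={"source": str(path)},
    )


def write_trace(trace: Trace, path) -> None:
    """Write a trace as TSV ('.gz' compresses); round-trips to 1e-9 relative."""
    path = Path(path)
    df = pd.DataFrame({
        "time_s": trace.time,
        "force_pN": trace.force,
        "extension_nm": trace.extension,
    })
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def write_ensemble(traces: list[Trace], manifest: dict, out_dir) -> Path:
    """Write all traces plus the manifest JSON; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for tr in traces:
        write_trace(tr, out / f"{tr.event_id}.tsv")
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj


def config_hash(config) -> str:
    """Stable short hash of a config dataclass/dict for provenance."""
    payload = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_results(bundle: dict, out_dir) -> Path:
    """Serialise a results bundle: one JSON plus TSV sidecars for tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_part = {}
    for key, val in bundle.items():
        if isinstance(val, pd.DataFrame):
            val.to_csv(out / f"{key}.tsv", sep="\t", index=False,
                       float_format="%.10g")
            json_part[key] = f"{key}.tsv"
        else:
            json_part[key] = _jsonable(val)
    path = out / "results.json"
    path.write_text(json.dumps(json_part, indent=1))
    return path
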