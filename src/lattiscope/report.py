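"""Consolidated, machine-readable report generation.

``build_report`` flattens the stage outputs (dataclasses, DataFrames, dicts,
arrays) into a deterministic JSON-serializable summary plus CSV tables, with
a run log carrying the seed, the configuration hash and every threshold
used, so that identical seed + configuration reproduce an identical report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib

import numpy as np
import pandas as pd


def _jsonable(obj):
    if obj is None or isinstance(obj, (bool, int, str)):
        return obj
    if isinstance(obj, float):
        return obj if np.isfinite(obj) else repr(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _jsonable(float(obj))
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)
                if not isinstance(getattr(obj, f.name),
                                  (pd.DataFrame, np.ndarray))
                or isinstance(getattr(obj, f.name), np.ndarray)
                and getattr(obj, f.name).size <= 512}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in sorted(obj.items(),
                                                        key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return {"table": True, "n_rows": int(len(obj)),
                "columns": list(obj.columns)}
    return repr(obj)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def build_report(outputs: dict, config: dict | None = None,
                 seed: int | None = None,
                 out_dir: str | pathlib.Path | None = None) -> dict:
    """Bundle stage outputs into a deterministic report.

    ``outputs`` maps metric names to stage results; every configured metric
    appears exactly once in the summary.  DataFrames found among the outputs
    are written as CSV next to the JSON when ``out_dir`` is given.  Raises on
    an empty output set.
    """
    if not outputs:
        raise ValueError("no stage outputs to report")
    config = config or {}
    report = {
        "run": {
            "seed": seed,
            "config_hash": config_hash(config),
            "config": _jsonable(config),
        },
        "metrics": {k: _jsonable(v) for k, v in sorted(outputs.items())},
    }
    if out_dir is not None:
        out_dir = pathlib.Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, value in outputs.items():
            if isinstance(value, pd.DataFrame):
                value.to_csv(out_dir / f"{name}.csv", index=False)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
    return report
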