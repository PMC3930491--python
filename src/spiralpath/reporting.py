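"""Report serialization: tidy CSV tables plus JSON summaries."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .experiments import Report

__all__ = ["write_report", "read_report_trials", "summary_json"]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def summary_json(report: Report) -> str:
    """JSON document with the aggregate table and run metadata."""
    return json.dumps(
        {
            "meta": _jsonable(report.meta),
            "summary": _jsonable(report.summary.to_dict(orient="records")),
        },
        indent=2,
    )


def write_report(report: Report, path: str | Path, format: str = "csv") -> None:
    """Write a report to disk.

    ``csv`` writes the raw per-trial table (one row per trial; an empty
    report yields a header-only file) and a side-car ``<stem>.summary.json``
    with aggregates and metadata.  ``json`` writes only the JSON summary.
    """
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        report.trials.to_csv(p, index=False)
        p.with_suffix(".summary.json").write_text(summary_json(report))
    elif format == "json":
        p.write_text(summary_json(report))
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report_trials(path: str | Path) -> pd.DataFrame:
    """Read back the raw trial table written by :func:`write_report`."""
    return pd.read_csv(path)
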