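"""Deterministic tabular/JSON report writing.

Every report is written both as a delimited table (fixed column order,
floats at a configurable precision, 4 decimals by default) and as a
versioned JSON document, so re-running on identical input yields
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_report", "round_floats", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1"


def round_floats(obj, precision: int = 4):
    """Recursively round floats inside nested dict/list/scalar structures."""
    if isinstance(obj, float):
        if not np.isfinite(obj):
            return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
        return round(obj, precision)
    if isinstance(obj, (np.floating,)):
        return round_floats(float(obj), precision)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return round_floats(obj.tolist(), precision)
    if isinstance(obj, dict):
        return {str(k): round_floats(v, precision) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [round_floats(v, precision) for v in obj]
    return obj


def write_report(
    results: pd.DataFrame,
    path_base: str | Path,
    name: str = "report",
    precision: int = 4,
    sep: str = "\t",
) -> tuple[Path, Path]:
    """Write *results* as ``<base>.tsv`` and ``<base>.json``.

    Returns the two paths.  An empty frame yields a header-only table.
    """
    base = Path(path_base)
    base.parent.mkdir(parents=True, exist_ok=True)
    table_path = base.with_suffix(".tsv")
    json_path = base.with_suffix(".json")
    results.to_csv(table_path, sep=sep, float_format=f"%.{precision}f")
    doc = {
        "schema_version": SCHEMA_VERSION,
        "name": name,
        "columns": [str(c) for c in results.columns],
        "index": [str(i) for i in results.index],
        "rows": round_floats(results.to_dict(orient="records"), precision),
    }
    with open(json_path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return table_path, json_path
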