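"""Response-table and report I/O.

CSV dialect: UTF-8, comma, header required.  One row per respondent per
administration with metadata columns (respondent_id, arm, site, sex, form,
diagnosis) and 1-based item columns item_1..item_65; a blank cell means the
item was not administered.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

META_COLUMNS = ["respondent_id", "arm", "site", "sex", "form", "diagnosis"]
_ITEM_RE = re.compile(r"^item_(\d+)$")


def item_columns(n_items: int = 65) -> list[str]:
    return [f"item_{i}" for i in range(1, n_items + 1)]


def validate_header(columns, n_items: int = 65) -> list[str]:
    """Check the response-table header; returns the item columns present."""
    columns = list(columns)
    missing = [c for c in META_COLUMNS if c not in columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    items, offending = [], []
    for c in columns:
        m = _ITEM_RE.match(c)
        if m:
            if not 1 <= int(m.group(1)) <= n_items:
                offending.append(c)
            else:
                items.append(c)
        elif c not in META_COLUMNS:
            offending.append(c)
    if offending:
        raise SchemaError(f"columns outside the schema: {offending}")
    if not items:
        raise SchemaError("no item columns found")
    return items


def read_responses(path, n_items: int = 65, kmax: int = 3) -> pd.DataFrame:
    """Read and validate a response CSV; item cells become floats with NaN
    for blanks.  Out-of-range scores raise with the offending line number."""
    df = pd.read_csv(path, dtype={"respondent_id": str})
    items = validate_header(df.columns, n_items)
    vals = df[items].to_numpy(dtype=float)
    bad = np.where(
        ~np.isnan(vals) & ((vals < 0) | (vals > kmax) | (vals != np.rint(vals)))
    )
    if bad[0].size:
        r, c = bad[0][0], bad[1][0]
        raise SchemaError(
            f"invalid item score {vals[r, c]} in column {items[c]} "
            f"on line {r + 2} of {path}"
        )
    return df


def write_responses(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for c in out.columns:
        if _ITEM_RE.match(c):
            out[c] = out[c].astype("Int64")
    out.to_csv(path, index=False)


def write_study(study, out_dir) -> dict:
    """Write a simulated study (bank.json, truth.json, roster.csv,
    responses.csv) and return the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "bank": out_dir / "bank.json",
        "truth": out_dir / "truth.json",
        "roster": out_dir / "roster.csv",
        "responses": out_dir / "responses.csv",
    }
    study.bank.to_json(paths["bank"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(study.truth, fh, indent=1)
    study.roster.to_csv(paths["roster"], index=False)
    write_responses(study.responses, paths["responses"])
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_summary_json(summary: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(summary), fh, indent=1, sort_keys=True)
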