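"""Trace persistence and provenance.

Traces are written as CSV or JSON-lines with a leading provenance record
(config hash, master seed, code version), fixed column order and fixed
float precision; ``read_trace(write_trace(t))`` reproduces the trace to
that precision.  A run repeated with identical config and seed produces a
bit-identical file.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__

__all__ = ["config_hash", "provenance", "write_trace", "read_trace"]

FLOAT_FORMAT = "%.10g"


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def provenance(config_obj, seed: int) -> dict:
    return {"config_hash": config_hash(config_obj), "seed": int(seed),
            "version": __version__}


def write_trace(trace: pd.DataFrame, path: str | Path, fmt: str = "csv",
                prov: Optional[dict] = None) -> Path:
    """Write an agent trace with an embedded provenance header line."""
    path = Path(path)
    header = "# provenance: " + json.dumps(prov or {}, sort_keys=True)
    if fmt == "csv":
        body = trace.to_csv(index=False, float_format=FLOAT_FORMAT)
        path.write_text(header + "\n" + body)
    elif fmt == "jsonl":
        lines = [json.dumps({"_meta": prov or {}}, sort_keys=True)]
        for row in trace.itertuples(index=False):
            d = {}
            for k, v in zip(trace.columns, row):
                if isinstance(v, float):
                    d[k] = float(FLOAT_FORMAT % v)
                elif hasattr(v, "item"):
                    d[k] = v.item()
                else:
                    d[k] = v
            lines.append(json.dumps(d))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown trace format {fmt!r}")
    return path


def read_trace(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a trace written by :func:`write_trace`; returns (trace, provenance)."""
    path = Path(path)
    text = path.read_text()
    first, _, rest = text.partition("\n")
    if first.startswith("# provenance:"):
        prov = json.loads(first[len("# provenance:"):])
        df = pd.read_csv(Path(path), comment="#")
        return df, prov
    if first.startswith("{") and "_meta" in first:
        prov = json.loads(first)["_meta"]
        rows = [json.loads(line) for line in rest.splitlines() if line.strip()]
        return pd.DataFrame(rows), prov
    # bare CSV without provenance
    return pd.read_csv(path), {}
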