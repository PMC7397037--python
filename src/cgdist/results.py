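"""JSON result records: versioned, deterministic, round-trippable.

Every stage output (a ``CgdIndex``, a ``DensityMeasurement``, ...) is
written as a JSON document with a schema version, the record type name,
the record fields, and the full run configuration echoed so any result
file is self-describing.  Keys are sorted, NaN is rejected before
anything touches disk, and rereading reconstructs the original record.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any

import numpy as np

from .config import RunConfig
from .errors import ValidationError

SCHEMA_VERSION = 1


def _jsonable(obj: Any) -> Any:
    """Convert dataclasses / numpy values to plain JSON types, rejecting NaN."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)
        }
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        obj = float(obj)
    if isinstance(obj, float):
        if math.isnan(obj) or math.isinf(obj):
            raise ValidationError("record contains a non-finite value")
        return obj
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (str, int, bool)) or obj is None:
        return obj
    raise ValidationError(f"cannot serialize value of type {type(obj).__name__}")


def _record_registry() -> dict[str, type]:
    # imported here to keep results.py free of circular imports
    from .zonal import CgdIndex, ZonalPartitionSummary
    from .spots import DensityMeasurement, WindowDensity
    from .stats import GroupComparison, GroupSummary
    from .de import DEGene, GoZScore

    return {
        cls.__name__: cls
        for cls in (
            CgdIndex,
            ZonalPartitionSummary,
            DensityMeasurement,
            WindowDensity,
            GroupComparison,
            GroupSummary,
            DEGene,
            GoZScore,
        )
    }


def write_results(record: Any, path: str | Path, config: RunConfig | None = None) -> None:
    """Write a stage output as a versioned JSON document.

    Validates (rejecting NaN/inf) before opening the file, so a bad record
    never leaves a partial file behind.
    """
    doc = {
        "schema_version": SCHEMA_VERSION,
        "record_type": type(record).__name__,
        "record": _jsonable(record),
        "config": _jsonable((config or RunConfig()).to_dict()),
    }
    text = json.dumps(doc, sort_keys=True, indent=1, allow_nan=False)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text + "\n")


def read_results(path: str | Path) -> Any:
    """Read a result document back; reconstructs the original record type
    when it is one of the known stage outputs, else returns the raw dict."""
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValidationError(f"unknown schema version {doc.get('schema_version')}")
    registry = _record_registry()
    cls = registry.get(doc.get("record_type", ""))
    rec = doc["record"]
    if cls is None:
        return rec
    return _rebuild(cls, rec)


def _rebuild(cls: type, data: dict[str, Any]) -> Any:
    kwargs = {}
    registry = _record_registry()
    for f in dataclasses.fields(cls):
        val = data[f.name]
        # nested known record lists (e.g. windows inside a density record)
        sub = getattr(f.type, "__name__", None)
        if isinstance(val, list) and val and isinstance(val[0], dict):
            inner = _guess_inner(f, registry)
            if inner is not None:
                val = [_rebuild(inner, v) for v in val]
        elif isinstance(val, dict):
            inner = _guess_inner(f, registry)
            if inner is not None:
                val = _rebuild(inner, val)
        kwargs[f.name] = val
    return cls(**kwargs)


def _guess_inner(f: dataclasses.Field, registry: dict[str, type]) -> type | None:
    # field type annotations are strings under `from __future__ import annotations`
    ann = str(f.type)
    for name, cls in registry.items():
        if name in ann:
            return cls
    return None
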