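"""Results document: JSON serialization plus a small schema validator.

The document carries the effective run configuration, the normalization
report, one record per solution, aggregate statistics and a termination
status, so downstream reverse-ecology analyses can consume runs as plain
tables.  The shipped schema (resources/results_schema.json) is enforced by
a minimal validator supporting the subset of JSON Schema the document
uses (type/required/properties/items/enum).
"""

from __future__ import annotations

import json
from importlib import resources as importlib_resources
from typing import Dict, List, Optional

from .errors import FormatError
from .inference import EnumerationResult, SeedSolution
from .reconciliation import NormalizationReport

TOOL_NAME = "seedkit"


def _solution_record(sol: SeedSolution) -> Dict:
    return {
        "seeds": sol.sorted_seeds(),
        "ne_valid": sol.ne_valid,
        "no_accumulation_valid": sol.no_accumulation_valid,
        "fba_flux": sol.fba_flux,
        "minimality": sol.minimality,
    }


def build_results_document(
    config: Dict,
    normalization: NormalizationReport,
    result: EnumerationResult,
    statistics: Optional[Dict] = None,
    version: str = "0.1.0",
) -> Dict:
    return {
        "tool": TOOL_NAME,
        "version": version,
        "config": config,
        "normalization": normalization.as_dict(),
        "solutions": [_solution_record(s) for s in result.solutions],
        "statistics": statistics,
        "status": result.status,
        "message": result.message,
    }


def write_results(doc: Dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=False)
        fh.write("\n")


def load_schema() -> Dict:
    ref = importlib_resources.files("seedkit.resources").joinpath("results_schema.json")
    return json.loads(ref.read_text())


_TYPE_MAP = {
    "object": dict,
    "array": list,
    "string": str,
    "boolean": bool,
    "integer": int,
    "number": (int, float),
    "null": type(None),
}


def _check(value, schema, path: str, errors: List[str]) -> None:
    stype = schema.get("type")
    if stype is not None:
        types = stype if isinstance(stype, list) else [stype]
        pytypes = tuple(
            t for name in types for t in (
                _TYPE_MAP[name] if isinstance(_TYPE_MAP[name], tuple) else (_TYPE_MAP[name],)
            )
        )
        ok = isinstance(value, pytypes)
        if ok and isinstance(value, bool) and "boolean" not in types:
            ok = False
        if not ok:
            errors.append(f"{path}: expected {types}, got {type(value).__name__}")
            return
    if "enum" in schema and value not in schema["enum"]:
        errors.append(f"{path}: {value!r} not in {schema['enum']}")
    if isinstance(value, dict):
        for req in schema.get("required", []):
            if req not in value:
                errors.append(f"{path}: missing required key {req!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in value:
                _check(value[key], sub, f"{path}.{key}", errors)
    if isinstance(value, list) and "items" in schema:
        for i, item in enumerate(value):
            _check(item, schema["items"], f"{path}[{i}]", errors)


def validate_results_document(doc: Dict) -> None:
    """Raise FormatError if ``doc`` violates the shipped schema."""
    errors: List[str] = []
    _check(doc, load_schema(), "$", errors)
    if errors:
        raise FormatError("results document invalid: " + "; ".join(errors[:10]))
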