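"""Attribute validation against a fixed JSON-Schema subset.

Case and label attributes are free-form JSON documents whose shape is
fixed per project by a schema. Only a small, flat subset of JSON Schema
is supported — deliberately, so that validation is deterministic and the
contract is easy to state:

* top level: ``type`` (must be ``object`` when ``properties`` is given),
  ``properties``, ``required``
* per property: ``type`` in {string, number, integer, boolean},
  ``enum``, ``minimum``, ``maximum``
* no nesting, no arrays, no conditional keywords

A schema using any other keyword is rejected up front with
:class:`UnsupportedSchemaError` rather than silently half-validated.
"""

from __future__ import annotations

from dataclasses import dataclass

_TOP_KEYWORDS = {"type", "properties", "required"}
_PROP_KEYWORDS = {"type", "enum", "minimum", "maximum"}
_SCALAR_TYPES = {"string", "number", "integer", "boolean"}


class UnsupportedSchemaError(ValueError):
    """Schema uses a keyword outside the supported subset."""


@dataclass(frozen=True)
class Violation:
    """One failed constraint: the offending field and what failed."""

    field: str
    message: str

    def __str__(self) -> str:
        return f"{self.field}: {self.message}"


def check_schema(schema: dict) -> None:
    """Reject schemas outside the supported subset."""
    if not isinstance(schema, dict):
        raise UnsupportedSchemaError(f"schema must be an object, got {type(schema).__name__}")
    unknown = set(schema) - _TOP_KEYWORDS
    if unknown:
        raise UnsupportedSchemaError(f"unsupported keyword(s): {sorted(unknown)}")
    if "type" in schema and schema["type"] != "object":
        raise UnsupportedSchemaError(f"top-level type must be 'object', got {schema['type']!r}")
    for name, prop in schema.get("properties", {}).items():
        if not isinstance(prop, dict):
            raise UnsupportedSchemaError(f"property {name!r} must be a schema object")
        unknown = set(prop) - _PROP_KEYWORDS
        if unknown:
            raise UnsupportedSchemaError(
                f"unsupported keyword(s) in property {name!r}: {sorted(unknown)}"
            )
        if "type" in prop and prop["type"] not in _SCALAR_TYPES:
            raise UnsupportedSchemaError(
                f"property {name!r}: type must be one of {sorted(_SCALAR_TYPES)}, "
                f"got {prop['type']!r} (nested objects/arrays unsupported)"
            )
    req = schema.get("required", [])
    if not isinstance(req, list) or not all(isinstance(r, str) for r in req):
        raise UnsupportedSchemaError("'required' must be a list of property names")


def _type_ok(value, typ: str) -> bool:
    if typ == "string":
        return isinstance(value, str)
    if typ == "boolean":
        return isinstance(value, bool)
    if typ == "integer":
        return isinstance(value, int) and not isinstance(value, bool)
    if typ == "number":
        return isinstance(value, (int, float)) and not isinstance(value, bool)
    return False


def validate_attributes(doc: dict, schema: dict) -> list[Violation]:
    """Validate a flat document; returns one :class:`Violation` per failing
    constraint (empty list means the document is valid).

    The empty schema ``{}`` accepts any document. Validation is
    deterministic and independent of document key order: violations are
    reported in (required order, then sorted property name) order.
    """
    check_schema(schema)
    violations: list[Violation] = []
    if not isinstance(doc, dict):
        return [Violation("<document>", f"must be an object, got {type(doc).__name__}")]

    for name in schema.get("required", []):
        if name not in doc:
            violations.append(Violation(name, "required property is missing"))

    props = schema.get("properties", {})
    for name in sorted(doc):
        if name not in props:
            continue  # unconstrained extra properties are allowed
        prop = props[name]
        value = doc[name]
        if "type" in prop and not _type_ok(value, prop["type"]):
            violations.append(
                Violation(name, f"expected {prop['type']}, got {type(value).__name__}")
            )
            continue
        if "enum" in prop and value not in prop["enum"]:
            violations.append(Violation(name, f"value {value!r} not in enum {prop['enum']}"))
        if "minimum" in prop and isinstance(value, (int, float)) and not isinstance(value, bool):
            if value < prop["minimum"]:
                violations.append(Violation(name, f"value {value} below minimum {prop['minimum']}"))
        if "maximum" in prop and isinstance(value, (int, float)) and not isinstance(value, bool):
            if value > prop["maximum"]:
                violations.append(Violation(name, f"value {value} above maximum {prop['maximum']}"))
    return violations
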