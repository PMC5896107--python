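"""Write-only MI-JSON exporter.

MI-JSON is the dialect viewer applications consume: a flat ``data`` list
holding each distinct interactor once, followed by one object per binary
interaction referencing its two interactors by id. The exact field names
are this library's own versioned dialect, documented by the packaged
schema file (``data/mijson-schema.json``), which is the contract every
document is checked against.

The support matrix makes this format write-only: :func:`read_mijson_attempt`
exists solely to enforce that, and always raises.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Any, Iterable, Optional

from .errors import CapabilityError
from .model import (
    BinaryInteraction,
    CvTerm,
    Feature,
    Interactor,
    Organism,
    Range,
)

DIALECT_VERSION = "1"


def load_schema() -> dict:
    """The packaged MI-JSON schema (the dialect's contract)."""
    with resources.files("miexchange.data").joinpath("mijson-schema.json").open() as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Subset-of-JSON-Schema checker (type / required / properties / items / enum)
# ---------------------------------------------------------------------------

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "boolean": bool,
    "number": (int, float),
}


def _check(value: Any, schema: dict, path: str, problems: list[str]) -> None:
    if "enum" in schema and value not in schema["enum"]:
        problems.append(f"{path}: {value!r} not in {schema['enum']}")
        return
    expected = schema.get("type")
    if expected is not None:
        py = _TYPES[expected]
        if not isinstance(value, py) or (expected == "number" and isinstance(value, bool)):
            problems.append(f"{path}: expected {expected}, got {type(value).__name__}")
            return
    if expected == "object":
        for key in schema.get("required", []):
            if key not in value:
                problems.append(f"{path}: missing required key {key!r}")
        props = schema.get("properties", {})
        for key, sub in props.items():
            if key in value:
                _check(value[key], sub, f"{path}.{key}", problems)
    elif expected == "array" and "items" in schema:
        for idx, item in enumerate(value):
            _check(item, schema["items"], f"{path}[{idx}]", problems)


def validate_mijson(document: dict, schema: Optional[dict] = None) -> list[str]:
    """Check a document against the packaged schema plus the referential
    invariants (unique interactors, resolvable participant references).
    Returns a list of problems; empty means valid."""
    if schema is None:
        schema = load_schema()
    problems: list[str] = []
    _check(document, schema, "$", problems)
    if problems:
        return problems
    interactor_ids: list[str] = []
    for obj in document["data"]:
        if obj.get("object") == "interactor":
            interactor_ids.append(obj["id"])
    if len(interactor_ids) != len(set(interactor_ids)):
        problems.append("duplicate interactor objects in data list")
    known = set(interactor_ids)
    for obj in document["data"]:
        if obj.get("object") == "interaction":
            for slot in ("interactorA", "interactorB"):
                ref = obj.get(slot)
                if ref not in known:
                    problems.append(f"interaction {obj.get('id')}: {slot} -> {ref!r} unresolved")
    return problems


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _cv_obj(term: Optional[CvTerm]) -> Optional[dict]:
    if term is None:
        return None
    obj: dict[str, Any] = {"short": term.short_name}
    if term.full_name:
        obj["full"] = term.full_name
    if term.mi_identifier:
        obj["id"] = term.mi_identifier
    return obj


def _organism_obj(org: Optional[Organism]) -> Optional[dict]:
    if org is None:
        return None
    obj: dict[str, Any] = {"taxid": org.taxid}
    if org.common_name:
        obj["common"] = org.common_name
    if org.scientific_name:
        obj["scientific"] = org.scientific_name
    return obj


def _range_str(r: Range) -> str:
    start = str(r.start.coordinate) if r.start.is_determinate() else "?"
    end = str(r.end.coordinate) if r.end.is_determinate() else "?"
    return f"{start}-{end}"


def _feature_obj(feature: Feature) -> dict:
    obj: dict[str, Any] = {}
    if feature.names:
        obj["name"] = feature.names[0].name
    if feature.feature_type is not None:
        obj["type"] = _cv_obj(feature.feature_type)
    obj["sequenceData"] = [_range_str(r) for r in feature.ranges]
    return obj


def _interactor_obj(interactor: Interactor, features: list[Feature]) -> dict:
    obj: dict[str, Any] = {
        "object": "interactor",
        "id": interactor.preferred_id.key(),
        "label": interactor.preferred_id.identifier,
        "type": _cv_obj(interactor.interactor_type),
    }
    organism = _organism_obj(interactor.organism)
    if organism is not None:
        obj["organism"] = organism
    if interactor.sequence:
        obj["sequence"] = interactor.sequence
    obj["features"] = [_feature_obj(f) for f in features]
    return obj


def write_mijson(interactions: Iterable[BinaryInteraction], indent: int = 2) -> str:
    """Serialize binaries as an MI-JSON document (text).

    Deterministic ordering: interactor objects sorted by preferred id, then
    interaction objects in input order. Each distinct interactor appears
    exactly once; participant features are aggregated onto their interactor.
    """
    interactions = list(interactions)
    interactors: dict[str, Interactor] = {}
    features: dict[str, list[Feature]] = {}
    for bi in interactions:
        for participant in bi.participants:
            key = participant.interactor.preferred_id.key()
            interactors.setdefault(key, participant.interactor)
            features.setdefault(key, []).extend(participant.features)

    data: list[dict] = [
        _interactor_obj(interactors[key], features[key]) for key in sorted(interactors)
    ]
    for idx, bi in enumerate(interactions, start=1):
        obj: dict[str, Any] = {
            "object": "interaction",
            "id": bi.id or f"interaction-{idx}",
            "interactorA": bi.participant_a.interactor.preferred_id.key(),
            "interactorB": bi.participant_b.interactor.preferred_id.key(),
        }
        if bi.interaction_type is not None:
            obj["interactionType"] = _cv_obj(bi.interaction_type)
        if bi.experiment is not None and bi.experiment.detection_method is not None:
            obj["detmethod"] = _cv_obj(bi.experiment.detection_method)
        source_ids = [x.key() for x in bi.xrefs]
        if bi.id:
            source_ids.insert(0, bi.id)
        obj["sourceIdentifiers"] = source_ids
        if bi.confidences:
            obj["confidences"] = [
                {"type": term.short_name, "value": value} for term, value in bi.confidences
            ]
        if bi.complex_expansion is not None:
            obj["expansion"] = _cv_obj(bi.complex_expansion)
        if bi.is_negative:
            obj["negative"] = True
        data.append(obj)

    document = {"format": "mi-json", "version": DIALECT_VERSION, "data": data}
    problems = validate_mijson(document)
    if problems:  # writer bug guard: output must always meet its own contract
        raise AssertionError(f"writer produced schema-invalid MI-JSON: {problems}")
    return json.dumps(document, indent=indent)


def read_mijson_attempt(stream: object = None) -> None:
    """MI-JSON is write-only; reading always raises (support-matrix
    enforcement, mirrored by the registry)."""
    raise CapabilityError("MI-JSON is write-only: no reader exists for this format")
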