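"""Reading and writing model definitions and analysis inputs.

The model definition is a single JSON document with four sections —
``tree``, ``attributes``, ``value_functions`` and ``weights`` — validated
structurally on load.  Serialisation is canonical (fixed field order,
sections sorted by id), so serialize -> parse -> serialize round-trips
byte-identically.

Performance tables and cost tables travel as plain CSV with a mandatory
header row: the first column is the option id.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .efficiency import CostProfile
from .scoring import ValueFunction, build_value_function
from .tree import Attribute, Cluster, PerformanceTable, ValueTree

SCHEMA = "mavt-model/1"


class ModelFormatError(ValueError):
    """The model document does not match the expected schema."""


@dataclass
class ModelDefinition:
    """Parsed model document: structure, scales and weights."""

    tree: ValueTree
    attributes: dict[str, Attribute]
    value_functions: dict[str, ValueFunction]
    weights: dict[str, float]  # raw weights as stored (typically 0-100)


def _require(doc: Mapping, key: str, section: str) -> object:
    if key not in doc:
        raise ModelFormatError(f"{section}: missing field {key!r}")
    return doc[key]


def parse_model(doc: Mapping) -> ModelDefinition:
    """Build a :class:`ModelDefinition` from a decoded JSON document."""
    if doc.get("schema") != SCHEMA:
        raise ModelFormatError(f"unsupported schema {doc.get('schema')!r}, expected {SCHEMA!r}")
    tdoc = _require(doc, "tree", "model")
    root = _require(tdoc, "root", "tree")
    clusters = tuple(
        Cluster(id=str(_require(c, "id", "cluster")),
                name=str(c.get("name", c["id"])),
                attributes=tuple(str(a) for a in _require(c, "attributes", "cluster")))
        for c in _require(tdoc, "clusters", "tree"))
    tree = ValueTree(root_id=str(_require(root, "id", "tree.root")),
                     root_name=str(root.get("name", root["id"])), clusters=clusters)

    attributes: dict[str, Attribute] = {}
    for a in _require(doc, "attributes", "model"):
        aid = str(_require(a, "id", "attribute"))
        attributes[aid] = Attribute(
            id=aid, name=str(a.get("name", aid)),
            cluster=str(a.get("cluster", tree.cluster_of(aid) or "")),
            metric=str(a.get("metric", "")), units=str(a.get("units", "")),
            kind=str(a.get("kind", "continuous")),
            direction=str(a.get("direction", "increasing")),
            minimum=a.get("minimum"), maximum=a.get("maximum"),
            lower_ref=a.get("lower_ref"), higher_ref=a.get("higher_ref"),
            levels=tuple(str(x) for x in a.get("levels", [])))

    value_functions: dict[str, ValueFunction] = {}
    for vf in doc.get("value_functions", []):
        aid = str(_require(vf, "attribute", "value_function"))
        if aid not in attributes:
            raise ModelFormatError(f"value_functions: unknown attribute {aid!r}")
        attr = attributes[aid]
        if "anchors" in vf:
            value_functions[aid] = build_value_function(
                attr, anchors=[(float(x), float(v)) for x, v in vf["anchors"]])
        elif "levels" in vf:
            value_functions[aid] = build_value_function(
                attr, level_scores={str(k): float(v) for k, v in vf["levels"].items()})
        else:
            raise ModelFormatError(f"value_functions[{aid}]: needs 'anchors' or 'levels'")

    weights = {str(k): float(v) for k, v in doc.get("weights", {}).items()}
    return ModelDefinition(tree=tree, attributes=attributes,
                           value_functions=value_functions, weights=weights)


def model_to_doc(model: ModelDefinition) -> dict:
    """Canonical plain-dict form of a model definition."""
    doc: dict = {
        "schema": SCHEMA,
        "tree": {
            "root": {"id": model.tree.root_id, "name": model.tree.root_name},
            "clusters": [
                {"id": c.id, "name": c.name, "attributes": list(c.attributes)}
                for c in model.tree.clusters
            ],
        },
        "attributes": [],
        "value_functions": [],
        "weights": {k: model.weights[k] for k in sorted(model.weights)},
    }
    for aid in sorted(model.attributes):
        a = model.attributes[aid]
        entry: dict = {
            "id": a.id, "name": a.name, "cluster": a.cluster,
            "metric": a.metric, "units": a.units,
            "kind": a.kind, "direction": a.direction,
        }
        if a.minimum is not None:
            entry["minimum"] = a.minimum
        if a.maximum is not None:
            entry["maximum"] = a.maximum
        entry["lower_ref"] = a.lower_ref
        entry["higher_ref"] = a.higher_ref
        if a.levels:
            entry["levels"] = list(a.levels)
        doc["attributes"].append(entry)
    for aid in sorted(model.value_functions):
        vf = model.value_functions[aid]
        if vf.is_ordinal:
            doc["value_functions"].append(
                {"attribute": aid, "levels": {k: vf.levels[k] for k in sorted(vf.levels)}})
        else:
            doc["value_functions"].append(
                {"attribute": aid, "anchors": [[x, v] for x, v in vf.anchors]})
    return doc


def dumps_model(model: ModelDefinition) -> str:
    return json.dumps(model_to_doc(model), indent=2, ensure_ascii=False) + "\n"


def load_model(path: str | Path) -> ModelDefinition:
    with open(path, encoding="utf-8") as fh:
        return parse_model(json.load(fh))


def save_model(model: ModelDefinition, path: str | Path) -> None:
    Path(path).write_text(dumps_model(model), encoding="utf-8")


def load_performance(path: str | Path) -> PerformanceTable:
    return PerformanceTable.from_csv(path)


def load_costs(path: str | Path) -> dict[str, CostProfile]:
    """Costs CSV: option, drug_cost, admin_cost[, total_cost]."""
    df = pd.read_csv(path)
    required = {"option", "drug_cost", "admin_cost"}
    missing = required - set(df.columns)
    if missing:
        raise ModelFormatError(f"costs CSV missing columns {sorted(missing)}")
    out: dict[str, CostProfile] = {}
    for _, row in df.iterrows():
        total = float(row["total_cost"]) if "total_cost" in df.columns and pd.notna(
            row.get("total_cost")) else None
        out[str(row["option"])] = CostProfile(
            option=str(row["option"]), drug_cost=float(row["drug_cost"]),
            admin_cost=float(row["admin_cost"]), total=total)
    return out


def load_judgment_csv(path: str | Path):
    """Judgment matrix CSV: stimulus ids as header/row labels, semantic
    category labels in the upper triangle, empty below the diagonal."""
    from .macbeth import JudgmentMatrix

    df = pd.read_csv(path, index_col=0, dtype=str)
    stimuli = [str(s) for s in df.index]
    if [str(c) for c in df.columns] != stimuli:
        raise ModelFormatError("judgment CSV must have identical row and column labels")
    judgments: dict[tuple[str, str], int | str] = {}
    for i, a in enumerate(stimuli):
        for j, b in enumerate(stimuli):
            if j <= i:
                continue
            cell = df.iat[i, j]
            if pd.isna(cell) or str(cell).strip() == "":
                raise ModelFormatError(f"judgment CSV: missing cell ({a}, {b})")
            judgments[(a, b)] = str(cell).strip()
    return JudgmentMatrix.from_judgments(stimuli, judgments)
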