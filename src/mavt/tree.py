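"""Value trees, attributes, options and performance tables.

A value tree organises the appraisal criteria of a multi-attribute value
model: a single root, one layer of value clusters (e.g. therapeutic impact,
safety profile), and leaf attributes.  Each attribute carries the metadata
needed to anchor an interval value scale: its measurement scale, preference
direction, natural range and the two reference levels ``x_l`` (scored 0)
and ``x_h`` (scored 100).

Validation is report-based rather than exception-based: structural problems
are collected into a :class:`ValidationReport` so a caller (or a facilitator
mid-workshop) can see every violation at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

CONTINUOUS = "continuous"
ORDINAL = "ordinal"
BINARY = "binary"
INCREASING = "increasing"
DECREASING = "decreasing"

_SCALE_KINDS = (CONTINUOUS, ORDINAL, BINARY)
_DIRECTIONS = (INCREASING, DECREASING)


@dataclass(frozen=True)
class Attribute:
    """A leaf criterion of the value tree.

    Parameters
    ----------
    id, name : str
        Unique identifier and display name.
    cluster : str
        Id of the value cluster this attribute belongs to.
    metric : str
        What is measured (e.g. "median overall survival").
    units : str
        Measurement units (months, % of patients, GBP, ...).
    kind : {"continuous", "ordinal", "binary"}
    direction : {"increasing", "decreasing"}
        Whether larger raw performances are preferred.
    minimum, maximum : float, optional
        Natural range for continuous attributes.
    lower_ref, higher_ref :
        Reference levels x_l and x_h anchoring value 0 and 100.  Numeric for
        continuous attributes, level labels for ordinal/binary ones.
    levels : tuple of str
        Ordered level labels (worst to best under ``direction=increasing``)
        for ordinal and binary attributes.
    """

    id: str
    name: str
    cluster: str
    metric: str = ""
    units: str = ""
    kind: str = CONTINUOUS
    direction: str = INCREASING
    minimum: float | None = None
    maximum: float | None = None
    lower_ref: float | str | None = None
    higher_ref: float | str | None = None
    levels: tuple[str, ...] = ()

    @property
    def is_numeric(self) -> bool:
        return self.kind == CONTINUOUS

    def level_index(self, label: str) -> int:
        """Position of an ordinal level label; comparison is by index."""
        return self.levels.index(label)


@dataclass(frozen=True)
class Cluster:
    id: str
    name: str
    attributes: tuple[str, ...]


@dataclass(frozen=True)
class ValueTree:
    """Single-root tree: root -> clusters -> leaf attributes."""

    root_id: str
    root_name: str
    clusters: tuple[Cluster, ...]

    def cluster_of(self, attribute_id: str) -> str | None:
        for c in self.clusters:
            if attribute_id in c.attributes:
                return c.id
        return None

    @property
    def leaf_ids(self) -> tuple[str, ...]:
        out: list[str] = []
        for c in self.clusters:
            out.extend(c.attributes)
        return tuple(out)


@dataclass(frozen=True)
class Option:
    id: str
    name: str = ""


@dataclass(frozen=True)
class Violation:
    code: str
    subject: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.subject}: {self.message}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations

    def add(self, code: str, subject: str, message: str) -> None:
        self.violations.append(Violation(code, subject, message))

    def codes(self) -> set[str]:
        return {v.code for v in self.violations}


class PerformanceTable:
    """Options x attributes matrix of raw performance levels.

    Backed by a pandas DataFrame (rows = options, columns = attributes);
    cells hold numbers for continuous attributes and level labels for
    ordinal/binary ones.
    """

    def __init__(self, data: pd.DataFrame):
        self.data = data.copy()
        self.data.index.name = "option"

    @classmethod
    def from_dict(cls, values: Mapping[str, Mapping[str, object]]) -> "PerformanceTable":
        """Build from {option id: {attribute id: level}}."""
        return cls(pd.DataFrame.from_dict(dict(values), orient="index"))

    @classmethod
    def from_csv(cls, path) -> "PerformanceTable":
        return cls(pd.read_csv(path, index_col=0))

    def to_csv(self, path) -> None:
        self.data.to_csv(path)

    @property
    def options(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def attributes(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    def value(self, option: str, attribute: str):
        return self.data.at[option, attribute]


def _improvement_ok(attr: Attribute) -> bool:
    """Moving from x_l to x_h must be an improvement under the direction."""
    if attr.lower_ref is None or attr.higher_ref is None:
        return False
    if attr.is_numeric:
        lo, hi = float(attr.lower_ref), float(attr.higher_ref)
        return hi > lo if attr.direction == INCREASING else hi < lo
    try:
        il = attr.level_index(str(attr.lower_ref))
        ih = attr.level_index(str(attr.higher_ref))
    except ValueError:
        return False
    return ih > il if attr.direction == INCREASING else ih < il


def validate_model(tree: ValueTree, attributes: Iterable[Attribute]) -> ValidationReport:
    """Structural validation of a value tree plus its attribute set.

    Returns a report; violations are entries, never exceptions.  A passing
    model is accepted by every downstream operation.
    """
    report = ValidationReport()
    attrs = list(attributes)
    by_id: dict[str, Attribute] = {}

    seen: set[str] = {tree.root_id}
    for c in tree.clusters:
        if c.id in seen:
            report.add("duplicate-id", c.id, "cluster id reused")
        seen.add(c.id)
    for a in attrs:
        if a.id in seen:
            report.add("duplicate-id", a.id, "attribute id collides with a node id")
        seen.add(a.id)
        if a.id in by_id:
            report.add("duplicate-attribute", a.id, "attribute defined twice")
        by_id[a.id] = a

    # each attribute in exactly one cluster, and cluster membership agrees
    leaf_count: dict[str, int] = {}
    for c in tree.clusters:
        for aid in c.attributes:
            leaf_count[aid] = leaf_count.get(aid, 0) + 1
            if aid not in by_id:
                report.add("unknown-leaf", aid, f"cluster {c.id} references undefined attribute")
    for aid, n in leaf_count.items():
        if n > 1:
            report.add("duplicate-leaf", aid, "attribute assigned to more than one cluster")
    for a in attrs:
        if leaf_count.get(a.id, 0) == 0:
            report.add("orphan-attribute", a.id, "attribute not attached to any cluster")
        declared = tree.cluster_of(a.id)
        if declared is not None and a.cluster and a.cluster != declared:
            report.add("cluster-mismatch", a.id,
                       f"attribute declares cluster {a.cluster!r} but sits under {declared!r}")

    for a in attrs:
        _validate_attribute(a, report)
    return report


def _validate_attribute(a: Attribute, report: ValidationReport) -> None:
    if a.kind not in _SCALE_KINDS:
        report.add("bad-scale-kind", a.id, f"unknown scale kind {a.kind!r}")
        return
    if a.direction not in _DIRECTIONS:
        report.add("bad-direction", a.id, f"unknown preference direction {a.direction!r}")
        return
    if a.kind == BINARY and len(a.levels) != 2:
        report.add("bad-levels", a.id, "binary attribute must declare exactly two levels")
    if a.kind == ORDINAL and len(a.levels) < 2:
        report.add("bad-levels", a.id, "ordinal attribute needs an ordered list of levels")
    if a.lower_ref is None or a.higher_ref is None:
        report.add("missing-reference", a.id, "both reference levels are required")
        return
    if a.lower_ref == a.higher_ref:
        report.add("degenerate reference interval", a.id, "x_l equals x_h")
        return
    if a.is_numeric:
        lo = a.minimum if a.minimum is not None else -float("inf")
        hi = a.maximum if a.maximum is not None else float("inf")
        for tag, x in (("lower_ref", a.lower_ref), ("higher_ref", a.higher_ref)):
            if not (lo <= float(x) <= hi):
                report.add("reference-out-of-range", a.id, f"{tag}={x} outside [{lo}, {hi}]")
    else:
        for tag, x in (("lower_ref", a.lower_ref), ("higher_ref", a.higher_ref)):
            if str(x) not in a.levels:
                report.add("reference-out-of-range", a.id, f"{tag}={x!r} not a declared level")
    if not _improvement_ok(a):
        report.add("reference-direction", a.id,
                   "moving from x_l to x_h is not an improvement under the stated direction")


def validate_performance(table: PerformanceTable,
                         tree: ValueTree,
                         attributes: Iterable[Attribute]) -> ValidationReport:
    """Completeness and range checks of a performance table against a model."""
    report = ValidationReport()
    by_id = {a.id: a for a in attributes}
    expected = set(tree.leaf_ids)

    missing_cols = expected - set(table.attributes)
    for aid in sorted(missing_cols):
        report.add("incomplete", aid, "attribute column missing from performance table")
    extra = set(table.attributes) - expected
    for aid in sorted(extra):
        report.add("unknown-attribute", aid, "performance column not in the model")

    for aid in sorted(expected & set(table.attributes)):
        a = by_id[aid]
        col = table.data[aid]
        for opt, x in col.items():
            if pd.isna(x):
                report.add("incomplete", f"{opt}/{aid}", "missing performance level")
            elif a.is_numeric:
                try:
                    v = float(x)
                except (TypeError, ValueError):
                    report.add("out of range", f"{opt}/{aid}", f"non-numeric level {x!r}")
                    continue
                lo = a.minimum if a.minimum is not None else -float("inf")
                hi = a.maximum if a.maximum is not None else float("inf")
                if not (lo <= v <= hi):
                    report.add("out of range", f"{opt}/{aid}", f"{v} outside [{lo}, {hi}]")
            else:
                if str(x) not in a.levels:
                    report.add("out of range", f"{opt}/{aid}", f"{x!r} not a declared level")
    return report
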