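"""Information-system data model, schema handling, table I/O and discretization.

An information system is a finite table ``I = (U, A ∪ D)``: a universe *U* of
objects described by a set *A* of condition attributes plus a single decision
attribute *D* (the class label).  Rough-set operations work on categorical
symbols, so numeric attributes carry ordered cut points and are mapped to
interval labels by :func:`discretize` before any indiscernibility computation.

Values are held internally as Python objects in a pandas DataFrame; a missing
cell is ``None``.  On disk a missing cell is a sentinel token (default ``"?"``,
the UCI convention).  The decision column may never be missing: rows with a
missing decision are dropped (and counted) at read time.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Sentinel token used for missing cells in CSV files (UCI convention).
DEFAULT_MISSING_TOKEN = "?"

CATEGORICAL = "categorical"
NUMERIC = "numeric"
CONDITION = "condition"
DECISION = "decision"


def _cut_label(cut: float | int | str) -> str:
    """Textual label for a cut point, preserving the schema's spelling."""
    if isinstance(cut, str):
        return cut
    return format(cut, "g")


@dataclass(frozen=True)
class AttributeSchema:
    """Declared name, kind and role of one table column.

    ``cut_points`` (numeric attributes only) are the ordered left edges of the
    discretization bins; they may be given as strings to pin the exact label
    spelling (``"0.80"`` stays ``"0.80"``).
    """

    name: str
    kind: str = CATEGORICAL
    role: str = CONDITION
    cut_points: tuple[float | int | str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in (CATEGORICAL, NUMERIC):
            raise ValueError(f"unknown attribute kind {self.kind!r} for {self.name!r}")
        if self.role not in (CONDITION, DECISION):
            raise ValueError(f"unknown attribute role {self.role!r} for {self.name!r}")
        if self.cut_points is not None:
            object.__setattr__(self, "cut_points", tuple(self.cut_points))
            values = self.cut_values
            if any(b <= a for a, b in zip(values, values[1:])):
                raise ValueError(f"cut_points of {self.name!r} must be strictly increasing")

    @property
    def cut_values(self) -> tuple[float, ...]:
        """Cut points as floats, in order."""
        if self.cut_points is None:
            return ()
        return tuple(float(c) for c in self.cut_points)

    @property
    def cut_labels(self) -> tuple[str, ...]:
        if self.cut_points is None:
            return ()
        return tuple(_cut_label(c) for c in self.cut_points)


@dataclass(frozen=True)
class InformationSystem:
    """A table ``I = (U, A ∪ D)`` of categorical (or not-yet-discretized) values.

    Attributes
    ----------
    object_ids:
        Ordered object labels (the universe *U*).
    attributes:
        Condition attribute schemas, in column order (the set *A*).
    decision:
        Schema of the single decision attribute *D*.
    values:
        ``|U| × |A|`` grid, indexed by object id and condition name.  Cells are
        strings after discretization, floats for not-yet-discretized numeric
        attributes, and ``None`` where missing.
    decision_values:
        One decision symbol per object; never missing.
    """

    object_ids: tuple[str, ...]
    attributes: tuple[AttributeSchema, ...]
    decision: AttributeSchema
    values: pd.DataFrame = field(repr=False)
    decision_values: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names) or self.decision.name in names:
            raise ValueError("attribute names must be unique")
        if self.decision.role != DECISION:
            raise ValueError("decision schema must have role='decision'")
        if any(a.role != CONDITION for a in self.attributes):
            raise ValueError("condition schemas must have role='condition'")
        if self.values.shape != (len(self.object_ids), len(self.attributes)):
            raise ValueError(
                f"value grid is {self.values.shape}, expected "
                f"{(len(self.object_ids), len(self.attributes))}"
            )
        if list(self.values.columns) != names:
            raise ValueError("value grid columns must match attribute order")
        if len(self.decision_values) != len(self.object_ids):
            raise ValueError("decision_values length must equal |U|")
        if self.decision_values.isna().any():
            raise ValueError("decision values may never be missing")

    # -- convenience ------------------------------------------------------

    @property
    def condition_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.attributes)

    @property
    def n_objects(self) -> int:
        return len(self.object_ids)

    def attribute(self, name: str) -> AttributeSchema:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(f"unknown attribute {name!r}")

    def has_missing(self) -> bool:
        return bool(self.values.isna().any().any())

    def decision_classes(self) -> tuple[str, ...]:
        """Distinct decision symbols in first-occurrence order."""
        seen: dict[str, None] = {}
        for v in self.decision_values:
            seen.setdefault(v, None)
        return tuple(seen)

    def to_frame(self, missing_token: str = DEFAULT_MISSING_TOKEN) -> pd.DataFrame:
        """Full table (conditions + decision) with missing cells as the sentinel."""
        out = self.values.copy()
        out = out.where(out.notna(), missing_token)
        out[self.decision.name] = self.decision_values
        return out

    def subset(
        self,
        object_ids: Sequence[str] | None = None,
        attribute_names: Sequence[str] | None = None,
    ) -> "InformationSystem":
        """Project onto a subset of objects and/or condition attributes."""
        ids = tuple(object_ids) if object_ids is not None else self.object_ids
        if attribute_names is None:
            attrs = self.attributes
        else:
            attrs = tuple(self.attribute(n) for n in attribute_names)
        cols = [a.name for a in attrs]
        return InformationSystem(
            object_ids=ids,
            attributes=attrs,
            decision=self.decision,
            values=self.values.loc[list(ids), cols],
            decision_values=self.decision_values.loc[list(ids)],
        )

    def equals(self, other: "InformationSystem") -> bool:
        return (
            self.object_ids == other.object_ids
            and self.attributes == other.attributes
            and self.decision == other.decision
            and self.values.equals(other.values)
            and self.decision_values.equals(other.decision_values)
        )


def build_information_system(
    rows: Sequence[Sequence[object]],
    attributes: Sequence[AttributeSchema],
    decision: AttributeSchema,
    decision_values: Sequence[str],
    object_ids: Sequence[str] | None = None,
) -> InformationSystem:
    """Assemble an :class:`InformationSystem` from in-memory rows."""
    ids = tuple(object_ids) if object_ids is not None else tuple(
        f"P{i + 1}" for i in range(len(rows))
    )
    frame = pd.DataFrame(
        list(rows), index=list(ids), columns=[a.name for a in attributes], dtype=object
    )
    return InformationSystem(
        object_ids=ids,
        attributes=tuple(attributes),
        decision=decision,
        values=frame,
        decision_values=pd.Series(list(decision_values), index=list(ids), dtype=object),
    )


# ---------------------------------------------------------------------------
# Schema files
# ---------------------------------------------------------------------------


def read_schema(path: str | Path) -> list[AttributeSchema]:
    """Read a YAML schema file: a list of name/kind/role/cut_points mappings."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list) or not raw:
        raise ValueError(f"schema file {path} must contain a non-empty list")
    schemas = []
    for entry in raw:
        schemas.append(
            AttributeSchema(
                name=str(entry["name"]),
                kind=entry.get("kind", CATEGORICAL),
                role=entry.get("role", CONDITION),
                cut_points=tuple(entry["cut_points"]) if entry.get("cut_points") else None,
            )
        )
    _validate_schema(schemas)
    return schemas


def write_schema(schemas: Sequence[AttributeSchema], path: str | Path) -> None:
    entries = []
    for s in schemas:
        entry: dict[str, object] = {"name": s.name, "kind": s.kind, "role": s.role}
        if s.cut_points is not None:
            entry["cut_points"] = list(s.cut_points)
        entries.append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)


def _validate_schema(schemas: Sequence[AttributeSchema]) -> None:
    names = [s.name for s in schemas]
    if len(set(names)) != len(names):
        raise ValueError("schema attribute names must be unique")
    n_decision = sum(s.role == DECISION for s in schemas)
    if n_decision != 1:
        raise ValueError(f"schema must declare exactly one decision attribute, got {n_decision}")


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------


def read_table(
    path: str | Path,
    schema: Sequence[AttributeSchema],
    *,
    missing_token: str = DEFAULT_MISSING_TOKEN,
    id_column: str | None = None,
) -> InformationSystem:
    """Read a CSV file (header row) into an :class:`InformationSystem`.

    Numeric columns are parsed to floats; categorical cells stay verbatim
    strings.  Cells equal to ``missing_token`` become missing.  Rows whose
    decision cell is missing are dropped with a logged count.  Object ids are
    taken from ``id_column`` when given, else synthesized as ``P1…Pn`` in row
    order.
    """
    _validate_schema(schema)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    if frame.shape[0] == 0:
        raise ValueError(f"empty dataset: {path} has no data rows")

    expected = [s.name for s in schema] + ([id_column] if id_column else [])
    unknown = [c for c in frame.columns if c not in expected]
    if unknown:
        raise ValueError(f"unknown column(s) {unknown} in {path}")
    absent = [c for c in expected if c not in frame.columns]
    if absent:
        raise ValueError(f"column(s) {absent} declared in schema but absent from {path}")

    decision_schema = next(s for s in schema if s.role == DECISION)
    conditions = tuple(s for s in schema if s.role == CONDITION)

    frame = frame.where(frame != missing_token, other=pd.NA)
    keep = frame[decision_schema.name].notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("read_table: dropped %d row(s) with missing decision value", n_dropped)
    frame = frame.loc[keep]
    if frame.shape[0] == 0:
        raise ValueError(f"empty dataset: {path} has no rows with a decision value")

    if id_column:
        ids = tuple(str(v) for v in frame[id_column])
    else:
        ids = tuple(f"P{i + 1}" for i in range(frame.shape[0]))
    frame.index = pd.Index(ids)

    values = pd.DataFrame(index=frame.index, dtype=object)
    for s in conditions:
        col = frame[s.name]
        if s.kind == NUMERIC:
            parsed = []
            for obj, cell in col.items():
                if pd.isna(cell):
                    parsed.append(None)
                    continue
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"non-numeric value {cell!r} for numeric attribute "
                        f"{s.name!r} (object {obj})"
                    ) from None
            values[s.name] = pd.Series(parsed, index=frame.index, dtype=object)
        else:
            values[s.name] = col.where(col.notna(), None).astype(object)

    decision_values = frame[decision_schema.name].astype(object)
    return InformationSystem(
        object_ids=ids,
        attributes=conditions,
        decision=decision_schema,
        values=values,
        decision_values=decision_values,
    )


def write_table(
    table: InformationSystem,
    path: str | Path,
    *,
    missing_token: str = DEFAULT_MISSING_TOKEN,
) -> None:
    """Write the table (conditions + decision column) back to CSV."""

    def fmt(cell: object) -> str:
        if cell is None or (isinstance(cell, float) and math.isnan(cell)):
            return missing_token
        if isinstance(cell, float):
            return format(cell, "g")
        return str(cell)

    out = table.values.map(fmt)
    out[table.decision.name] = table.decision_values
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------


def discretize(
    table: InformationSystem,
    schema: Sequence[AttributeSchema] | None = None,
) -> InformationSystem:
    """Map numeric attribute values onto cut-point labels.

    The convention is left-edge binning: a value maps to the label of the
    greatest cut point that does not exceed it, and values below the first cut
    point clamp to the first label.  Categorical attributes pass through
    unchanged, which makes the operation idempotent.  Missing cells stay
    missing.
    """
    by_name = {s.name: s for s in schema} if schema is not None else {}
    new_attrs: list[AttributeSchema] = []
    values = table.values.copy()
    for attr in table.attributes:
        spec = by_name.get(attr.name, attr)
        if attr.kind != NUMERIC:
            new_attrs.append(attr)
            continue
        if spec.cut_points is None:
            raise ValueError(f"numeric attribute {attr.name!r} has no cut_points")
        cuts = spec.cut_values
        labels = spec.cut_labels
        col = []
        for cell in values[attr.name]:
            if cell is None or (isinstance(cell, float) and math.isnan(cell)):
                col.append(None)
                continue
            # rightmost cut <= value, clamped to the first bin below range
            i = bisect.bisect_right(cuts, float(cell)) - 1
            col.append(labels[max(i, 0)])
        values[attr.name] = pd.Series(col, index=values.index, dtype=object)
        new_attrs.append(replace(attr, kind=CATEGORICAL, cut_points=spec.cut_points))
    return InformationSystem(
        object_ids=table.object_ids,
        attributes=tuple(new_attrs),
        decision=table.decision,
        values=values,
        decision_values=table.decision_values,
    )


# ---------------------------------------------------------------------------
# Reduct bitmasks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReductBitmask:
    """An attribute subset encoded as 0/1 flags over a fixed attribute sequence."""

    sequence: tuple[str, ...]
    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.bits):
            raise ValueError("bitmask length must match attribute sequence length")
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("bitmask entries must be 0 or 1")

    @property
    def attribute_set(self) -> frozenset[str]:
        return frozenset(n for n, b in zip(self.sequence, self.bits) if b)

    @property
    def size(self) -> int:
        return sum(self.bits)

    def __str__(self) -> str:
        return "[" + " ".join(str(b) for b in self.bits) + "]"


def write_reduct_bitmask(
    reduct: Iterable[str], sequence: Sequence[str]
) -> ReductBitmask:
    """Encode an attribute subset over a fixed sequence; bit i = 1 iff present."""
    reduct_set = set(reduct)
    extra = reduct_set - set(sequence)
    if extra:
        raise ValueError(f"reduct attribute(s) {sorted(extra)} not in sequence")
    return ReductBitmask(
        sequence=tuple(sequence),
        bits=tuple(1 if n in reduct_set else 0 for n in sequence),
    )
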