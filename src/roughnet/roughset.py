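"""Rough-set feature selection: indiscernibility partitions, approximations,
positive region, and exhaustive reduct enumeration.

Given an information system ``I = (U, A ∪ D)``, the indiscernibility relation
``IND(P)`` of an attribute subset ``P ⊆ A`` groups objects that take equal
values on every attribute of ``P``; its equivalence classes partition the
universe.  The lower approximation of a decision class is the union of blocks
wholly inside the class, the upper approximation the union of blocks touching
it, and the positive region ``Pos_A(D)`` the union of all classes' lower
approximations — the objects the full attribute set classifies with certainty.

A subset is accepted as a *reduct* when its indiscernibility structure matches
that of the full attribute set.  Two acceptance semantics are provided:

``"restricted"`` (default)
    ``IND(P)`` restricted to ``Pos_A(D)`` equals ``IND(A)`` restricted to the
    same universe.  This is the partition-comparison reading under which the
    bundled six-object heart sample yields exactly the reducts {Chp, Vessel}
    and {ECG, Vessel}.
``"pos_preserving"``
    the classical decision-relative criterion ``Pos_P(D) = Pos_A(D)``.

In approximate mode a subset is accepted when its similarity to the full
partition exceeds a threshold (strictly).  The default similarity is the
fraction of unordered object pairs on which the two partitions agree (a
Rand-type score, 1.0 iff identical); the dependency-degree ratio
``γ_P / γ_A`` is available as an alternative measure.

Accepted subsets are *not* filtered for minimality: any proper superset of an
exact reduct is itself accepted (superset closure), so reduct lists routinely
run up to size ``|A| − 1``.  The core is the intersection of all accepted
subsets.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .core import InformationSystem, ReductBitmask, write_reduct_bitmask

# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Partition:
    """Equivalence classes of an indiscernibility relation over a universe."""

    universe: frozenset[str]
    blocks: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for b in self.blocks:
            if not b:
                raise ValueError("partition blocks must be nonempty")
            if seen & b:
                raise ValueError("partition blocks must be pairwise disjoint")
            seen |= b
        if seen != self.universe:
            raise ValueError("partition blocks must cover the universe exactly")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_of(self, object_id: str) -> frozenset[str]:
        for b in self.blocks:
            if object_id in b:
                return b
        raise KeyError(f"{object_id!r} not in universe")

    def as_sets(self) -> set[frozenset[str]]:
        return set(self.blocks)


@dataclass(frozen=True)
class ApproximationSet:
    """Lower/upper approximation and boundary region of one decision class."""

    class_label: str
    lower: frozenset[str]
    upper: frozenset[str]
    boundary: frozenset[str]

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise ValueError("lower approximation must be contained in the upper")
        if self.boundary != self.upper - self.lower:
            raise ValueError("boundary must equal upper minus lower")


@dataclass(frozen=True)
class PositiveRegion:
    """Objects classifiable with certainty: the union of all lower approximations."""

    ids: frozenset[str]


@dataclass(frozen=True)
class SubsetCount:
    """Combinatorial accounting of candidate subsets: S = 2^n − 2, C(n, k) per size."""

    n: int
    total: int
    per_size: dict[int, int] = field(compare=False)


@dataclass(frozen=True)
class Reduct:
    attributes: frozenset[str]
    size: int
    score: float


@dataclass(frozen=True)
class ReductReport:
    """Outcome of an exhaustive reduct search."""

    mode: Literal["exact", "approx"]
    threshold: float | None
    semantics: str
    measure: str
    reducts: tuple[Reduct, ...]
    core: frozenset[str]
    counts: SubsetCount
    reference_universe: frozenset[str]

    def reduct_sets(self) -> list[frozenset[str]]:
        return [r.attributes for r in self.reducts]

    def per_size_tally(self) -> dict[int, int]:
        """Number of accepted subsets at each size (the shape of a reduct-count table)."""
        tally: dict[int, int] = {}
        for r in self.reducts:
            tally[r.size] = tally.get(r.size, 0) + 1
        return tally

    def to_dict(self, sequence: Sequence[str] | None = None) -> dict:
        """JSON-ready report; with a `sequence`, reducts also carry bitmask strings."""
        entries = []
        for r in self.reducts:
            entry: dict[str, object] = {
                "attributes": sorted(r.attributes),
                "size": r.size,
                "score": r.score,
            }
            if sequence is not None:
                entry["bitmask"] = list(write_reduct_bitmask(r.attributes, sequence).bits)
            entries.append(entry)
        return {
            "mode": self.mode,
            "threshold": self.threshold,
            "semantics": self.semantics,
            "measure": self.measure,
            "subset_counts": {
                "n": self.counts.n,
                "total": self.counts.total,
                "per_size": {str(k): v for k, v in sorted(self.counts.per_size.items())},
            },
            "n_reducts": len(self.reducts),
            "per_size_reducts": {str(k): v for k, v in sorted(self.per_size_tally().items())},
            "core": sorted(self.core),
            "reference_universe": sorted(self.reference_universe),
            "reducts": entries,
        }


# ---------------------------------------------------------------------------
# Partitions and approximations
# ---------------------------------------------------------------------------


def _check_no_missing(table: InformationSystem, attrs: Sequence[str]) -> None:
    if attrs and table.values[list(attrs)].isna().any().any():
        raise ValueError("table has MISSING cells; run preprocessing first")


def ind_partition(
    table: InformationSystem,
    attrs: Iterable[str],
    universe: Iterable[str] | None = None,
) -> Partition:
    """Partition of the universe by the indiscernibility relation IND(attrs).

    Objects share a block iff they agree on every attribute of ``attrs``; the
    empty attribute set induces the single-block partition.
    """
    attrs = tuple(attrs)
    unknown = set(attrs) - set(table.condition_names)
    if unknown:
        raise ValueError(f"attribute(s) {sorted(unknown)} not in the condition set")
    ids = tuple(universe) if universe is not None else table.object_ids
    stray = set(ids) - set(table.object_ids)
    if stray:
        raise ValueError(f"object(s) {sorted(stray)} not in the universe")
    _check_no_missing(table, attrs)

    groups: dict[tuple, list[str]] = {}
    if attrs:
        sub = table.values.loc[list(ids), list(attrs)]
        for obj, row in zip(ids, sub.itertuples(index=False, name=None)):
            groups.setdefault(row, []).append(obj)
    else:
        groups[()] = list(ids)
    return Partition(
        universe=frozenset(ids),
        blocks=tuple(frozenset(g) for g in groups.values()),
    )


def approximations(
    table: InformationSystem, attrs: Iterable[str], class_label: str
) -> ApproximationSet:
    """Lower/upper approximation and boundary of one decision class under IND(attrs)."""
    members = frozenset(
        obj for obj, d in zip(table.object_ids, table.decision_values) if d == class_label
    )
    if not members:
        raise ValueError(f"unknown class label {class_label!r}")
    partition = ind_partition(table, attrs)
    lower: set[str] = set()
    upper: set[str] = set()
    for block in partition.blocks:
        if block & members:
            upper |= block
            if block <= members:
                lower |= block
    return ApproximationSet(
        class_label=class_label,
        lower=frozenset(lower),
        upper=frozenset(upper),
        boundary=frozenset(upper - lower),
    )


def positive_region(table: InformationSystem, attrs: Iterable[str]) -> PositiveRegion:
    """Union over decision classes of the lower approximations under IND(attrs)."""
    partition = ind_partition(table, attrs)
    decisions = table.decision_values
    pos: set[str] = set()
    for block in partition.blocks:
        labels = {decisions.loc[o] for o in block}
        if len(labels) == 1:
            pos |= block
    return PositiveRegion(ids=frozenset(pos))


# ---------------------------------------------------------------------------
# Combinatorial accounting
# ---------------------------------------------------------------------------


def subset_counts(n: int) -> SubsetCount:
    """Candidate accounting for n attributes: S = 2^n − 2 proper nonempty subsets,
    C(n, k) of them at each size k in 1..n−1."""
    if n < 1:
        raise ValueError("attribute count must be at least 1")
    return SubsetCount(
        n=n,
        total=2**n - 2,
        per_size={k: math.comb(n, k) for k in range(1, n)},
    )


# ---------------------------------------------------------------------------
# Partition similarity
# ---------------------------------------------------------------------------


def _pair_counts(labels: np.ndarray) -> int:
    """Number of unordered object pairs lying together under the labelling."""
    counts = np.bincount(labels)
    return int((counts * (counts - 1) // 2).sum())


def _pair_similarity(labels_p: np.ndarray, labels_q: np.ndarray) -> float:
    """Fraction of unordered pairs on which two labellings agree (together/apart)."""
    n = labels_p.shape[0]
    total = n * (n - 1) // 2
    if total == 0:
        return 1.0
    together_p = _pair_counts(labels_p)
    together_q = _pair_counts(labels_q)
    # pairs together under both = pairs within cells of the joint labelling
    joint = labels_p.astype(np.int64) * (int(labels_q.max()) + 1) + labels_q
    _, joint_inv = np.unique(joint, return_inverse=True)
    together_both = _pair_counts(joint_inv)
    agree = total - together_p - together_q + 2 * together_both
    return agree / total


def partition_similarity(p: Partition, q: Partition) -> float:
    """Pairwise (Rand-type) agreement between two partitions of the same universe.

    Symmetric, in [0, 1], and equal to 1.0 iff the partitions are identical.
    """
    if p.universe != q.universe:
        raise ValueError("partitions must share the same universe")
    if len(p.universe) < 2:
        raise ValueError("similarity needs at least 2 objects")
    ids = sorted(p.universe)
    index = {o: i for i, o in enumerate(ids)}

    def labels(part: Partition) -> np.ndarray:
        arr = np.empty(len(ids), dtype=np.int64)
        for k, block in enumerate(part.blocks):
            for o in block:
                arr[index[o]] = k
        return arr

    return _pair_similarity(labels(p), labels(q))


# ---------------------------------------------------------------------------
# Reduct enumeration
# ---------------------------------------------------------------------------


def _encode(table: InformationSystem) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes for condition values (objects × attributes) and decisions."""
    _check_no_missing(table, table.condition_names)
    cols = []
    for name in table.condition_names:
        codes, _ = pd.factorize(table.values[name].astype(str))
        cols.append(codes)
    codes = (
        np.column_stack(cols).astype(np.int64)
        if cols
        else np.empty((table.n_objects, 0), dtype=np.int64)
    )
    dec, _ = pd.factorize(table.decision_values.astype(str))
    return codes, dec.astype(np.int64)


def _combine(labels: np.ndarray, col: np.ndarray) -> np.ndarray:
    """Canonical group labels of the pair (labels, col): one id per distinct pair."""
    key = labels.astype(np.int64) * (int(col.max()) + 1) + col
    _, inv = np.unique(key, return_inverse=True)
    return inv


def _group_labels(codes: np.ndarray, subset: Sequence[int]) -> np.ndarray:
    labels = codes[:, subset[0]]
    _, labels = np.unique(labels, return_inverse=True)
    for j in subset[1:]:
        labels = _combine(labels, codes[:, j])
    return labels


def _pure_mask(labels: np.ndarray, decisions: np.ndarray) -> np.ndarray:
    """Boolean mask of objects lying in a decision-pure block of the labelling."""
    n_blocks = int(labels.max()) + 1 if labels.size else 0
    lo = np.full(n_blocks, np.iinfo(np.int64).max, dtype=np.int64)
    hi = np.full(n_blocks, np.iinfo(np.int64).min, dtype=np.int64)
    np.minimum.at(lo, labels, decisions)
    np.maximum.at(hi, labels, decisions)
    return (lo == hi)[labels]


def find_reducts(
    table: InformationSystem,
    mode: Literal["exact", "approx"] = "exact",
    threshold: float = 0.90,
    size_range: tuple[int, int] | None = None,
    *,
    semantics: Literal["restricted", "pos_preserving"] = "restricted",
    measure: Literal["pairs", "gamma"] = "pairs",
    max_attributes: int = 20,
) -> ReductReport:
    """Exhaustively enumerate attribute subsets and accept reducts.

    Every proper nonempty subset of the condition set (2^|A| − 2 candidates,
    optionally limited to ``size_range``) is examined in size-ascending order.
    In ``"exact"`` mode a subset is accepted when its indiscernibility matches
    that of the full attribute set under the chosen ``semantics``; in
    ``"approx"`` mode when its similarity exceeds ``threshold`` strictly.  No
    minimality filter is applied, so exact-mode acceptance is superset-closed.
    """
    names = table.condition_names
    n = len(names)
    counts = subset_counts(n) if n >= 1 else SubsetCount(0, 0, {})
    if size_range is None and n > max_attributes:
        raise ValueError(
            f"{n} attributes exceed the exhaustive-search cap of {max_attributes}; "
            "pass a size_range or raise max_attributes"
        )

    codes, decisions = _encode(table)
    index = {o: i for i, o in enumerate(table.object_ids)}

    if n >= 1:
        labels_full = _group_labels(codes, list(range(n)))
        pos_mask_full = _pure_mask(labels_full, decisions)
    else:  # degenerate, no condition attributes
        labels_full = np.zeros(table.n_objects, dtype=np.int64)
        pos_mask_full = np.zeros(table.n_objects, dtype=bool)
    reference_universe = frozenset(
        o for o in table.object_ids if pos_mask_full[index[o]]
    )
    ref = pos_mask_full
    labels_full_ref = labels_full[ref]
    if labels_full_ref.size:
        _, labels_full_ref = np.unique(labels_full_ref, return_inverse=True)
    n_blocks_full_ref = int(labels_full_ref.max()) + 1 if labels_full_ref.size else 0
    gamma_full = int(pos_mask_full.sum())

    lo_size, hi_size = size_range if size_range is not None else (1, max(n - 1, 0))
    lo_size = max(lo_size, 1)
    hi_size = min(hi_size, n - 1)

    def _restricted_pair_score(labels: np.ndarray) -> float:
        sub = labels[ref]
        if sub.size < 2:
            return 1.0
        _, sub = np.unique(sub, return_inverse=True)
        return _pair_similarity(sub, labels_full_ref)

    def score_subset(labels: np.ndarray) -> tuple[bool, float]:
        """(exact acceptance, graded similarity) of IND(subset) vs IND(A)."""
        if semantics == "pos_preserving":
            pos_mask = _pure_mask(labels, decisions)
            exact = bool(np.array_equal(pos_mask, pos_mask_full))
            if exact:
                return True, 1.0
            if measure == "gamma":
                score = (pos_mask.sum() / gamma_full) if gamma_full else 0.0
            else:
                score = _restricted_pair_score(labels)
            return False, float(min(score, 1.0))
        if measure == "gamma":
            pos_mask = _pure_mask(labels, decisions)
            score = (pos_mask.sum() / gamma_full) if gamma_full else 1.0
            return score >= 1.0, float(min(score, 1.0))
        sub = labels[ref]
        if sub.size < 2:
            return True, 1.0
        _, sub = np.unique(sub, return_inverse=True)
        # IND(A)|ref refines IND(P)|ref, so equality <=> equal block counts
        if int(sub.max()) + 1 == n_blocks_full_ref:
            return True, 1.0
        return False, _pair_similarity(sub, labels_full_ref)

    accepted: list[Reduct] = []
    prev_level: dict[tuple[int, ...], np.ndarray] = {}
    for size in range(1, hi_size + 1):
        level: dict[tuple[int, ...], np.ndarray] = {}
        for subset in itertools.combinations(range(n), size):
            if size == 1:
                _, labels = np.unique(codes[:, subset[0]], return_inverse=True)
            else:
                labels = _combine(prev_level[subset[:-1]], codes[:, subset[-1]])
            level[subset] = labels
            if size < lo_size:
                continue
            exact, score = score_subset(labels)
            ok = exact if mode == "exact" else score > threshold
            if ok:
                accepted.append(
                    Reduct(
                        attributes=frozenset(names[j] for j in subset),
                        size=size,
                        score=float(score),
                    )
                )
        prev_level = level

    accepted.sort(key=lambda r: (r.size, sorted(r.attributes)))
    core = (
        frozenset.intersection(*(r.attributes for r in accepted))
        if accepted
        else frozenset()
    )
    return ReductReport(
        mode=mode,
        threshold=threshold if mode == "approx" else None,
        semantics=semantics,
        measure=measure,
        reducts=tuple(accepted),
        core=core,
        counts=counts,
        reference_universe=reference_universe,
    )
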