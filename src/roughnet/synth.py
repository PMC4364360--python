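"""Synthetic categorical information systems with known ground truth.

The generator emulates the structure of small clinical tables after
discretization: a handful of categorical condition attributes, a binary
decision, optional decision inconsistency (so the boundary region is
nonempty) and MCAR missing cells.  Crucially the generative recipe plants a
known minimal reduct, so feature selection can be tested as parameter
recovery:

* *informative* attributes are drawn i.i.d. uniform over a small alphabet and
  the decision is a fixed (seeded) lookup table over their joint values —
  by construction the label depends on nothing else;
* each *redundant* attribute is a bijective recoding of one informative
  attribute, so its indiscernibility partition is identical to its source's
  and the two are interchangeable inside any reduct;
* *noise* attributes are independent of everything.

``inconsistency_rate`` flips the labels of that fraction of objects, which
makes IND(A)-blocks class-mixed wherever a flipped object shares its full
attribute profile with an unflipped one.  ``missing_rate`` masks condition
cells independently (the decision is never masked).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AttributeSchema, DECISION, InformationSystem, build_information_system


@dataclass(frozen=True)
class SynthSpec:
    n_objects: int = 100
    n_informative: int = 2
    n_redundant: int = 1
    n_noise: int = 2
    values_per_attribute: int = 3
    inconsistency_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_objects < 1 or self.n_informative < 1:
            raise ValueError("need at least 1 object and 1 informative attribute")
        if min(self.n_redundant, self.n_noise) < 0 or self.values_per_attribute < 1:
            raise ValueError("counts must be non-negative, cardinality at least 1")
        for rate in (self.inconsistency_rate, self.missing_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.values_per_attribute**self.n_informative < 2:
            raise ValueError("decision cannot vary: cardinality^n_informative < 2")


@dataclass(frozen=True)
class SynthTruth:
    """Planted structure: the minimal reduct and which attribute recodes which."""

    minimal_reduct: frozenset[str]
    redundancy_map: dict[str, str]  # redundant name -> informative source
    decision_table: dict[tuple[str, ...], str]
    flipped_objects: frozenset[str]


def gen_info_system(spec: SynthSpec) -> tuple[InformationSystem, SynthTruth]:
    """Generate a categorical information system with a planted minimal reduct."""
    rng = np.random.default_rng(spec.seed)
    card = spec.values_per_attribute
    alphabet = [f"v{i}" for i in range(card)]

    inf_names = [f"inf{i + 1}" for i in range(spec.n_informative)]
    red_names = [f"red{i + 1}" for i in range(spec.n_redundant)]
    noise_names = [f"noise{i + 1}" for i in range(spec.n_noise)]

    inf_codes = rng.integers(0, card, size=(spec.n_objects, spec.n_informative))

    # seeded lookup table over the informative value-tuples; forced non-constant
    tuples = list(itertools.product(range(card), repeat=spec.n_informative))
    labels = rng.integers(0, 2, size=len(tuples))
    if labels.min() == labels.max():
        labels[rng.integers(0, len(tuples))] = 1 - labels[0]
    decision_table = {
        tuple(alphabet[v] for v in t): str(lab) for t, lab in zip(tuples, labels)
    }
    tuple_index = {t: i for i, t in enumerate(tuples)}
    decisions = [
        str(labels[tuple_index[tuple(row)]]) for row in inf_codes.tolist()
    ]

    redundancy_map: dict[str, str] = {}
    columns: dict[str, list[str]] = {}
    for i, name in enumerate(inf_names):
        columns[name] = [alphabet[v] for v in inf_codes[:, i]]
    for name in red_names:
        src_idx = int(rng.integers(0, spec.n_informative))
        redundancy_map[name] = inf_names[src_idx]
        perm = rng.permutation(card)  # bijective recoding of the source alphabet
        columns[name] = [f"w{perm[v]}" for v in inf_codes[:, src_idx]]
    for name in noise_names:
        columns[name] = [alphabet[v] for v in rng.integers(0, card, size=spec.n_objects)]

    n_flip = int(round(spec.inconsistency_rate * spec.n_objects))
    flip_idx = rng.choice(spec.n_objects, size=n_flip, replace=False) if n_flip else []
    for i in flip_idx:
        decisions[i] = "1" if decisions[i] == "0" else "0"

    names = inf_names + red_names + noise_names
    attributes = [AttributeSchema(name=n) for n in names]
    decision = AttributeSchema(name="class", role=DECISION)
    rows = [[columns[n][i] for n in names] for i in range(spec.n_objects)]
    table = build_information_system(rows, attributes, decision, decisions)

    truth = SynthTruth(
        minimal_reduct=frozenset(inf_names),
        redundancy_map=redundancy_map,
        decision_table=decision_table,
        flipped_objects=frozenset(table.object_ids[i] for i in flip_idx),
    )
    if spec.missing_rate > 0:
        table = inject_missing(table, spec.missing_rate, seed=spec.seed + 1)
    return table, truth


def inject_missing(
    table: InformationSystem, rate: float, seed: int = 0
) -> InformationSystem:
    """Mask each condition cell independently with probability `rate` (MCAR);
    the decision column is never masked."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = rng.random(table.values.shape) < rate
    values = table.values.copy()
    arr = values.to_numpy(dtype=object)
    arr[mask] = None
    values = pd.DataFrame(arr, index=values.index, columns=values.columns, dtype=object)
    return InformationSystem(
        object_ids=table.object_ids,
        attributes=table.attributes,
        decision=table.decision,
        values=values,
        decision_values=table.decision_values,
    )


def gen_classification(
    n: int, d: int, class_separation: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Two integer-coded clusters on a 1–10 scale at a stated separation.

    Features mimic ordinal clinical scores: each class is a Gaussian cloud
    (sd 1) around its centre, rounded to integers and clipped to [1, 10].
    ``class_separation`` is the centre-to-centre distance per feature in
    coding units; 0 makes the classes indistinguishable.
    """
    if n < 4 or d < 1:
        raise ValueError("need n >= 4 and d >= 1")
    rng = np.random.default_rng(seed)
    c0 = rng.uniform(2.0, 3.5, size=d)
    c1 = np.minimum(c0 + class_separation, 10.0)
    n1 = n // 2
    n0 = n - n1
    X0 = rng.normal(c0, 1.0, size=(n0, d))
    X1 = rng.normal(c1, 1.0, size=(n1, d))
    X = np.vstack([X0, X1])
    y = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    X = np.clip(np.rint(X), 1, 10).astype(int)
    perm = rng.permutation(n)
    return X[perm], y[perm]
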