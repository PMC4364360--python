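"""End-to-end orchestration: preprocess → discretize → reducts → train → evaluate.

The pipeline mirrors the two-stage design of the method: a feature-selection
stage (missing-value handling, discretization, exhaustive reduct search) and
a classification stage (one backpropagation network per selected reduct and
train/test split ratio, 10-fold cross-validation inside the training portion,
final retrain on the whole training portion before the held-out evaluation).

Reduct selection is an explicit hand-off: the caller names the reducts to
carry into classification (or asks for the top-k by training-CV accuracy via
``top_k_by_cv`` — a convenience that is knowingly circular, since it selects
on the very signal later reported).  With neither given, the pipeline stops
after the reduct report.

All artifacts are deterministic functions of the configuration and its seed;
the metrics grid always carries an "All features" baseline row.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import bpnn, evaluation, roughset
from .core import (
    InformationSystem,
    read_schema,
    read_table,
    discretize,
    write_table,
)
from .preprocess import MissingReport, handle_missing

logger = logging.getLogger(__name__)

ALL_FEATURES = "All features"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on, in one serializable object."""

    data: str
    schema: str
    missing_threshold: float = 0.25
    reduct_mode: str = "exact"
    reduct_threshold: float = 0.90
    reduct_size_range: tuple[int, int] | None = None
    semantics: str = "restricted"
    selected_reducts: tuple[tuple[str, ...], ...] | None = None
    top_k_by_cv: int | None = None
    split_fractions: tuple[float, ...] = (0.8, 0.7, 0.6)
    k_folds: int = 10
    network: dict = field(default_factory=dict)
    positive_label: str | None = None
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "selected_reducts" in raw and raw["selected_reducts"] is not None:
            raw["selected_reducts"] = tuple(tuple(r) for r in raw["selected_reducts"])
        if "reduct_size_range" in raw and raw["reduct_size_range"] is not None:
            raw["reduct_size_range"] = tuple(raw["reduct_size_range"])
        if "split_fractions" in raw:
            raw["split_fractions"] = tuple(raw["split_fractions"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: RunConfig
    config_hash: str
    clean_table: InformationSystem
    missing_report: MissingReport
    reduct_report: roughset.ReductReport
    metrics_grid: pd.DataFrame | None  # rows: reduct label; cols: split fraction
    cv_grid: pd.DataFrame | None  # mean training-CV accuracy, same shape
    best: dict | None  # best-cell summary: confusion + metrics + ROC AUC


# ---------------------------------------------------------------------------
# Feature encoding
# ---------------------------------------------------------------------------


def encode_features(table: InformationSystem, attrs: Sequence[str]) -> np.ndarray:
    """Integer-code categorical columns: sorted distinct symbols → 0..m−1.

    Sorting makes the encoding independent of row order, so train/test
    projections of the same table agree.
    """
    cols = []
    for name in attrs:
        col = table.values[name]
        if col.isna().any():
            raise ValueError(f"attribute {name!r} has MISSING cells")
        symbols = sorted({str(v) for v in col})
        mapping = {s: i for i, s in enumerate(symbols)}
        cols.append([mapping[str(v)] for v in col])
    return np.asarray(cols, dtype=float).T


def binary_labels(table: InformationSystem, positive_label: str) -> np.ndarray:
    classes = table.decision_classes()
    if positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} not among classes {classes}")
    if len(classes) != 2:
        raise ValueError(f"binary classification requires 2 classes, got {len(classes)}")
    return np.asarray([1 if d == positive_label else 0 for d in table.decision_values])


def default_positive_label(table: InformationSystem) -> str:
    """Minority decision class (ties: first occurrence) — in the clinical
    benchmarks the disease outcome is the rarer label."""
    counts: dict[str, int] = {}
    for d in table.decision_values:
        counts[d] = counts.get(d, 0) + 1
    return min(counts, key=counts.get)


def _derived_seed(base: int, *key: int) -> int:
    state = np.random.SeedSequence(entropy=base, spawn_key=tuple(key)).generate_state(1)
    return int(state[0]) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# Classification stage helpers
# ---------------------------------------------------------------------------


def _evaluate_reduct(
    table: InformationSystem,
    attrs: Sequence[str],
    fraction: float,
    config: RunConfig,
    positive: str,
    seed: int,
) -> dict:
    """Split, cross-validate within the training portion, retrain, test."""
    X = encode_features(table, attrs)
    y = binary_labels(table, positive)
    ids = list(table.object_ids)
    index = {o: i for i, o in enumerate(ids)}
    spec = evaluation.SplitSpec(
        train_fraction=fraction, k_folds=config.k_folds, seed=seed
    )
    train_ids, test_ids = evaluation.split(ids, spec)
    tr = [index[o] for o in train_ids]
    te = [index[o] for o in test_ids]

    net_kwargs = dict(config.network)
    net_kwargs.setdefault("seed", _derived_seed(config.seed, 1))
    net = bpnn.NetworkConfig(n_inputs=len(attrs), **net_kwargs)

    # 10-fold CV inside the training portion validates the training phase
    cv_acc = None
    if len(train_ids) >= config.k_folds:
        folds = evaluation.kfold(train_ids, spec)
        accs = []
        for held in folds:
            held_set = set(held)
            fit_idx = [index[o] for o in train_ids if o not in held_set]
            val_idx = [index[o] for o in held]
            model, _ = bpnn.train_bpnn(X[fit_idx], y[fit_idx], net)
            _, pred = bpnn.predict(model, X[val_idx])
            accs.append(float(np.mean(pred == y[val_idx])))
        cv_acc = float(np.mean(accs))

    model, record = bpnn.train_bpnn(X[tr], y[tr], net)
    scores, pred = bpnn.predict(model, X[te])
    cm = evaluation.confusion(y[te].tolist(), pred.tolist(), 1)
    try:
        roc = evaluation.roc_auc(scores, y[te].tolist(), 1)
        auc = roc.auc
    except ValueError:  # single-class test fold
        auc = None
    mets = evaluation.metrics(cm, auc=auc)
    return {
        "attributes": list(attrs),
        "fraction": fraction,
        "n_train": len(tr),
        "n_test": len(te),
        "cv_accuracy": cv_acc,
        "confusion": {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn},
        "metrics": mets.rounded(),
        "raw_metrics": {
            "accuracy": mets.accuracy,
            "sensitivity": mets.sensitivity,
            "specificity": mets.specificity,
            "tpr": mets.tpr,
            "fpr": mets.fpr,
            "auc": mets.auc,
        },
        "train_epochs": len(record.mse),
        "stop_reason": record.stop_reason,
    }


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(name, exc) from exc
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return out

    return wrap


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages; see the module docstring for the contract."""
    cfg_hash = config.config_hash()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def dump(name: str, payload: dict) -> None:
        if out_dir:
            stamped = {"config_hash": cfg_hash, "seed": config.seed, **payload}
            (out_dir / name).write_text(json.dumps(stamped, indent=2, sort_keys=True))

    schema = _stage("load_schema")(read_schema, config.schema)
    table = _stage("read_table")(read_table, config.data, schema)
    logger.info("loaded %d objects × %d conditions (seed %d, config %s)",
                table.n_objects, len(table.attributes), config.seed, cfg_hash)

    clean, missing_report = _stage("preprocess")(
        handle_missing, table, config.missing_threshold
    )
    clean = _stage("discretize")(discretize, clean, schema)
    if out_dir:
        write_table(clean, out_dir / "clean.csv")
        dump("missing_report.json", {"report": missing_report.to_dict()})

    size_range = config.reduct_size_range
    report = _stage("reducts")(
        roughset.find_reducts,
        clean,
        mode=config.reduct_mode,
        threshold=config.reduct_threshold,
        size_range=size_range,
        semantics=config.semantics,
    )
    dump("reducts.json", {"report": report.to_dict(sequence=clean.condition_names)})

    # --- reduct hand-off -------------------------------------------------
    selections: list[tuple[str, tuple[str, ...]]] = []
    if config.selected_reducts is not None:
        for i, attrs in enumerate(config.selected_reducts, start=1):
            unknown = set(attrs) - set(clean.condition_names)
            if unknown:
                raise StageError(
                    "select",
                    ValueError(f"unknown attribute(s) {sorted(unknown)} in selected reduct"),
                )
            selections.append((f"R{i}", tuple(attrs)))
    elif config.top_k_by_cv is not None:
        positive = config.positive_label or default_positive_label(clean)
        ranked = []
        for r in report.reducts:
            attrs = tuple(sorted(r.attributes))
            res = _evaluate_reduct(
                clean, attrs, config.split_fractions[0], config, positive,
                _derived_seed(config.seed, 2),
            )
            ranked.append((res["cv_accuracy"] or 0.0, attrs))
        ranked.sort(key=lambda t: (-t[0], t[1]))
        selections = [
            (f"R{i}", attrs)
            for i, (_, attrs) in enumerate(ranked[: config.top_k_by_cv], start=1)
        ]

    if not selections:
        dump("run_meta.json", {"stages": ["preprocess", "discretize", "reducts"]})
        return PipelineResult(
            config, cfg_hash, clean, missing_report, report, None, None, None
        )

    # --- classification stage -------------------------------------------
    positive = config.positive_label or default_positive_label(clean)
    rows = selections + [(ALL_FEATURES, tuple(clean.condition_names))]
    grid = pd.DataFrame(index=[lab for lab, _ in rows],
                        columns=list(config.split_fractions), dtype=float)
    cv_grid = grid.copy()
    cells: dict[str, dict] = {}
    best_key, best_acc = None, -1.0
    for ri, (label, attrs) in enumerate(rows):
        for fi, fraction in enumerate(config.split_fractions):
            res = _stage(f"classify[{label},{fraction}]")(
                _evaluate_reduct, clean, attrs, fraction, config, positive,
                _derived_seed(config.seed, 3, ri, fi),
            )
            grid.loc[label, fraction] = res["raw_metrics"]["accuracy"]
            cv_grid.loc[label, fraction] = res["cv_accuracy"]
            cells[f"{label}@{fraction}"] = res
            if res["raw_metrics"]["accuracy"] > best_acc:
                best_acc = res["raw_metrics"]["accuracy"]
                best_key = f"{label}@{fraction}"

    best = {"cell": best_key, **cells[best_key]}
    if out_dir:
        grid.to_csv(out_dir / "metrics_grid.csv", index_label="reduct")
        cv_grid.to_csv(out_dir / "cv_grid.csv", index_label="reduct")
    dump("metrics.json", {"positive_label": positive, "cells": cells, "best": best})
    dump("run_meta.json", {"stages": ["preprocess", "discretize", "reducts", "classify"]})
    return PipelineResult(
        config, cfg_hash, clean, missing_report, report, grid, cv_grid, best
    )
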