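"""Confusion-table metrics, stratified cross-validation, parameter sweeps,
and the end-to-end pipeline driver.

Cross-validation pools the confusion counts of the held-out folds into a
single report (micro pooling) rather than averaging per-fold metrics, and by
default applies resampling to the training portion of each fold only, after
the split; ``resample_all=True`` balances the whole dataset up front
instead.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import features_188d, sequence_io
from .exceptions import ConfigurationError, ContractError
from .ghknn import GHKNNClassifier, GHKNNParams
from .resampling import ResampleConfig, balance_dataset

log = logging.getLogger(__name__)

SWEEPABLE = ("lam", "gamma", "mu")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ContractError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    sn: float
    sp: float
    acc: float
    mcc: float
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        return {
            "sn": self.sn, "sp": self.sp, "acc": self.acc, "mcc": self.mcc,
            "tp": self.counts.tp, "tn": self.counts.tn,
            "fp": self.counts.fp, "fn": self.counts.fn,
        }


def confusion(y_true, y_pred, positive_label) -> ConfusionCounts:
    """Standard 2x2 counts with respect to *positive_label*."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ContractError(
            f"length mismatch: {y_true.shape} true vs {y_pred.shape} predicted"
        )
    labels = set(np.unique(y_true)) | set(np.unique(y_pred))
    if len(labels) > 2:
        raise ContractError(f"more than 2 labels present: {sorted(labels)!r}")
    pos_t = y_true == positive_label
    pos_p = y_pred == positive_label
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """SN, SP, ACC and MCC from a 2x2 table; zero-denominator metrics are 0.

    Products inside the MCC root are exact integer arithmetic, so the float
    result is reproducible bit-for-bit.
    """
    if counts.total == 0:
        raise ContractError("metrics undefined for all-zero counts")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sn = tp / (fn + tp) if (fn + tp) else 0.0
    sp = tn / (fp + tn) if (fp + tn) else 0.0
    acc = (tn + tp) / counts.total
    denom_sq = (tn + fn) * (tp + fn) * (tn + fp) * (tp + fp)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom_sq) if denom_sq else 0.0
    return MetricsReport(sn=sn, sp=sp, acc=acc, mcc=mcc, counts=counts)


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    params: GHKNNParams | None = None,
    n_folds: int = 5,
    seed: int = 0,
    resample: ResampleConfig | None = None,
    resample_all: bool = False,
    positive_label=None,
) -> MetricsReport:
    """Stratified k-fold CV with pooled confusion counts.

    Resampling (when configured) happens inside each fold on the training
    rows only, with a per-fold seed offset, unless ``resample_all`` is set,
    in which case the whole dataset is balanced before splitting (the
    leakage-prone variant, kept for protocol comparisons).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if n_folds < 2:
        raise ContractError(f"n_folds must be >= 2, got {n_folds}")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ContractError(f"binary labels required, got {classes!r}")
    if positive_label is None:
        positive_label = classes[-1]
    if params is None:
        params = GHKNNParams()

    if resample is not None and resample_all:
        X, y = balance_dataset(X, y, resample)
        classes, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ContractError(
            f"smallest class has {counts.min()} rows; cannot stratify "
            f"into {n_folds} folds"
        )

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    tp = tn = fp = fn = 0
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        X_train, y_train = X[train_idx], y[train_idx]
        if resample is not None and not resample_all:
            X_train, y_train = balance_dataset(
                X_train, y_train,
                dataclasses.replace(resample, seed=resample.seed + fold),
            )
        clf = GHKNNClassifier(params).fit(X_train, y_train)
        y_pred = clf.predict(X[test_idx])
        c = confusion(y[test_idx], y_pred, positive_label)
        tp, tn, fp, fn = tp + c.tp, tn + c.tn, fp + c.fp, fn + c.fn
    return metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))


def sweep_parameter(
    X: np.ndarray,
    y: np.ndarray,
    params: GHKNNParams,
    which: str,
    grid: Sequence[float],
    n_folds: int = 5,
    seed: int = 0,
    resample: ResampleConfig | None = None,
    resample_all: bool = False,
) -> pd.DataFrame:
    """One-parameter-at-a-time CV sweep; other parameters stay fixed.

    Returns a data frame with columns ``value, sn, sp, acc, mcc``.
    """
    if which not in SWEEPABLE:
        raise ContractError(f"which must be one of {SWEEPABLE}, got {which!r}")
    grid = list(grid)
    if not grid:
        raise ContractError("grid must be non-empty")
    for v in grid:
        if which in ("lam", "gamma") and not v > 0:
            raise ConfigurationError(f"{which} grid value {v} must be > 0")
        if which == "mu" and v < 0:
            raise ConfigurationError(f"mu grid value {v} must be >= 0")
    rows = []
    for v in grid:
        report = cross_validate(
            X, y, dataclasses.replace(params, **{which: v}),
            n_folds=n_folds, seed=seed,
            resample=resample, resample_all=resample_all,
        )
        rows.append(
            {"value": v, "sn": report.sn, "sp": report.sp,
             "acc": report.acc, "mcc": report.mcc}
        )
    return pd.DataFrame(rows)


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _read_labels(path: str | Path) -> dict[str, object]:
    df = pd.read_csv(path, sep="\t")
    if not {"id", "label"} <= set(df.columns):
        raise ConfigurationError(f"label file {path} needs 'id' and 'label' columns")
    return dict(zip(df["id"].astype(str), df["label"]))


def run_pipeline(config) -> dict[str, Path]:
    """Execute extract -> balance -> cross-validate from a PipelineConfig.

    Writes into ``config.out_dir``: the feature table (when starting from
    FASTA), ``metrics.json``, an optional sweep CSV, and ``run.log`` with
    every parameter, seed, and input digest.  Returns the written paths.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    log_lines = [f"seed={config.seed}", f"params={config.params}"]

    if config.features:
        ids, X, y = sequence_io.read_feature_table(config.features)
        log_lines.append(f"features={config.features} sha256:{_digest(config.features)}")
    elif config.fasta:
        if not config.labels:
            raise ConfigurationError("a labels file is required with FASTA input")
        records = sequence_io.read_fasta(config.fasta)
        label_map = _read_labels(config.labels)
        missing = [r.id for r in records if r.id not in label_map]
        if missing:
            raise ConfigurationError(f"no label for records {missing[:5]!r}...")
        y = np.asarray([label_map[r.id] for r in records])
        X = features_188d.extract_many(records, descriptor=config.descriptor)
        feat_path = out_dir / "features.tsv"
        sequence_io.write_feature_table(records, X, y, feat_path)
        written["features"] = feat_path
        log_lines.append(f"fasta={config.fasta} sha256:{_digest(config.fasta)}")
        log_lines.append(f"labels={config.labels} sha256:{_digest(config.labels)}")
    else:
        raise ConfigurationError("config must name either a feature table or a FASTA file")

    resample = config.resample if config.resample_enabled else None
    log_lines.append(f"resample={resample} resample_all={config.resample_all}")

    report = cross_validate(
        X, y, config.params,
        n_folds=config.n_folds, seed=config.seed,
        resample=resample, resample_all=config.resample_all,
    )
    payload = report.to_dict()
    payload["params"] = dataclasses.asdict(config.params)
    payload["seed"] = config.seed
    payload["n_folds"] = config.n_folds
    payload["resample_enabled"] = config.resample_enabled
    payload["resample_all"] = config.resample_all
    metrics_path = out_dir / "metrics.json"
    metrics_path.write_text(json.dumps(payload, indent=2) + "\n")
    written["metrics"] = metrics_path

    if config.sweep_which:
        table = sweep_parameter(
            X, y, config.params, config.sweep_which, config.sweep_grid,
            n_folds=config.n_folds, seed=config.seed,
            resample=resample, resample_all=config.resample_all,
        )
        sweep_path = out_dir / f"sweep_{config.sweep_which}.csv"
        table.to_csv(sweep_path, index=False)
        written["sweep"] = sweep_path
        log_lines.append(f"sweep which={config.sweep_which} grid={list(config.sweep_grid)}")

    log_path = out_dir / "run.log"
    log_path.write_text("\n".join(log_lines) + "\n")
    written["log"] = log_path
    return written
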