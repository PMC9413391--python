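"""End-to-end plumbing: record -> fiducials -> features -> model -> report.

These helpers chain the single-purpose modules so the command-line tool,
the test suite and the reproduction script all execute the same code path.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from afsync import ecg_io, features as feat, preprocess
from afsync.delineate import delineate_record
from afsync.ecg_io import ClassLabel, EcgRecord, partition_dataset
from afsync.evaluate import evaluate_model, select_threshold
from afsync.model import DenseAF, TrainConfig

logger = logging.getLogger(__name__)


def record_features(rec: EcgRecord, lead_set: str = "twelve",
                    condition: bool = True, mains_freq: float = 50.0) -> pd.Series:
    """Preprocess, delineate and featurize one record.

    Raises ValueError when fewer than three R-waves are found (the record
    is then rejected upstream with a logged reason).
    """
    sig = (preprocess.preprocess_record(rec.signals, rec.fs, mains_freq)
           if condition else rec.signals)
    fid = delineate_record(sig, rec.leads, rec.fs)
    return feat.extract_features(sig, rec.leads, fid, lead_set)


def dataset_features(records: list[EcgRecord], lead_set: str = "twelve",
                     condition: bool = True) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature matrix and binary AF labels for a list of records.

    Records failing delineation (too few beats) are dropped with a warning.
    """
    rows, labels, index = [], [], []
    for rec in records:
        label = ecg_io.map_codes_to_class(rec.codes)
        if label == ClassLabel.EXCLUDED:
            continue
        try:
            vec = record_features(rec, lead_set, condition)
        except ValueError as exc:
            logger.warning("record %s rejected: %s", rec.record_id, exc)
            continue
        rows.append(vec)
        labels.append(1 if label == ClassLabel.AF else 0)
        index.append(rec.record_id)
    X = pd.DataFrame(rows, index=index)
    return X, np.asarray(labels)


def split_features(X: pd.DataFrame, y: np.ndarray,
                   manifest: pd.DataFrame, seed: int = 0):
    """Patient-wise 70/20/10 split of a feature table, returning the three
    (X, y) pairs in train/validation/test order."""
    recs = [(rid, manifest.set_index("record_id").loc[rid, "patient_id"],
             ClassLabel.AF if y[i] else ClassLabel.NON_AF)
            for i, rid in enumerate(X.index)]
    split = partition_dataset(recs, seed=seed)
    out = []
    for ids in (split.train, split.validation, split.test):
        keep = [rid for rid in X.index if rid in set(ids)]
        mask = X.index.isin(keep)
        out.append((X.loc[mask], y[mask]))
    return out


def train_and_select(X_tr: pd.DataFrame, y_tr: np.ndarray,
                     X_val: pd.DataFrame, y_val: np.ndarray,
                     widths: tuple[int, ...], lead_set: str = "twelve",
                     config: TrainConfig | None = None) -> DenseAF:
    """Train one architecture and set its threshold at max validation BAC."""
    config = config or TrainConfig()
    model = DenseAF(X_tr.shape[1], widths, config,
                    feature_names=list(X_tr.columns), lead_set=lead_set)
    model.fit(X_tr.to_numpy(), y_tr, X_val.to_numpy(), y_val)
    model.p_thr = select_threshold(model.predict_proba(X_val.to_numpy()), y_val)
    return model


def run_synthetic_study(n_records: int = 200, af_fraction: float = 0.08,
                        seed: int = 0, widths: tuple[int, ...] = (16, 8),
                        lead_set: str = "twelve",
                        duration_s: float = 20.0) -> dict:
    """Full synthetic study: generate, featurize, split, train, evaluate.

    Returns the trained model, the split feature tables and the test-set
    metric report (a Table-3-style frame with a Total row).
    """
    from afsync.synth import generate_dataset

    data, manifest = generate_dataset(n_records, af_fraction, seed,
                                      duration_s=duration_s)
    X, y = dataset_features([rec for rec, _ in data], lead_set)
    (X_tr, y_tr), (X_val, y_val), (X_te, y_te) = split_features(
        X, y, manifest, seed=seed)
    config = TrainConfig(seed=seed)
    model = train_and_select(X_tr, y_tr, X_val, y_val, widths, lead_set, config)
    report = evaluate_model(model, X_te.to_numpy(), y_te)
    return {"model": model, "manifest": manifest, "report": report,
            "train": (X_tr, y_tr), "validation": (X_val, y_val),
            "test": (X_te, y_te)}
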