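"""Shapley-value feature attribution for the trained classifier.

A prediction is decomposed into per-feature contributions (in probability
units) using the classic coalition-game weights: the Shapley value of
feature i is the average of its marginal contribution f(S u {i}) - f(S)
over all coalitions S not containing i, weighted |S|!(M-|S|-1)!/M!.
Missing features are marginalized over a background sample: f(S) is the
mean model output with the features in S fixed to the explained record and
the remainder drawn from each background row.

Exact enumeration (2^M coalitions) is used for small feature counts; a
permutation-sampling estimator with Monte-Carlo standard errors covers the
50-feature twelve-lead model.  Global importance is the mean absolute
Shapley value per feature over a dataset, reported alongside its
percent-of-max.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EXACT_LIMIT = 15


def value_function(predict_fn, x: np.ndarray, subset: np.ndarray,
                   background: np.ndarray) -> float:
    """Expected model output with the features in ``subset`` fixed to ``x``.

    ``subset`` is a boolean mask; features outside it take each background
    row's values and the outputs are averaged (marginal expectation).
    """
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] == 0:
        raise ValueError("background must be non-empty")
    x = np.asarray(x, dtype=float)
    grid = background.copy()
    grid[:, subset] = x[subset]
    return float(np.mean(predict_fn(grid)))


def _coalition_values(predict_fn, x: np.ndarray, background: np.ndarray) -> np.ndarray:
    """f(S) for every coalition bitmask, evaluated in one batched call."""
    m = x.size
    background = np.atleast_2d(background)
    n_bg = background.shape[0]
    rows = np.empty((2 ** m * n_bg, m))
    for s in range(2 ** m):
        mask = np.array([(s >> i) & 1 for i in range(m)], dtype=bool)
        block = background.copy()
        block[:, mask] = x[mask]
        rows[s * n_bg:(s + 1) * n_bg] = block
    preds = predict_fn(rows)
    return preds.reshape(2 ** m, n_bg).mean(axis=1)


def shapley_exact(predict_fn, x: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Exact Shapley values by full coalition enumeration (M <= 15).

    Satisfies efficiency (values sum to f(x) minus the base value),
    symmetry and the dummy axiom by construction.
    """
    x = np.asarray(x, dtype=float).ravel()
    m = x.size
    if m > EXACT_LIMIT:
        raise ValueError(
            f"{m} features exceed the exact-enumeration limit {EXACT_LIMIT}; "
            "use shapley_sampled")
    f = _coalition_values(predict_fn, x, background)
    fact = [math.factorial(k) for k in range(m + 1)]
    shap = np.zeros(m)
    for s in range(2 ** m):
        size = bin(s).count("1")
        for i in range(m):
            if s >> i & 1:
                continue
            w = fact[size] * fact[m - size - 1] / fact[m]
            shap[i] += w * (f[s | (1 << i)] - f[s])
    return shap


@dataclass
class SampledShap:
    """Permutation-sampling estimate with per-feature Monte-Carlo errors."""

    values: np.ndarray
    stderr: np.ndarray
    n_permutations: int


def shapley_sampled(predict_fn, x: np.ndarray, background: np.ndarray,
                    n_permutations: int = 2000, seed: int = 0) -> SampledShap:
    """Unbiased permutation-sampling estimator of the Shapley values.

    For each sampled permutation the features are inserted in order and the
    successive marginal contributions are credited to the inserted feature;
    averaging over permutations recovers the coalition-weighted sum.
    Deterministic given ``seed``.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations for a stable estimate")
    x = np.asarray(x, dtype=float).ravel()
    m = x.size
    background = np.atleast_2d(np.asarray(background, dtype=float))
    n_bg = background.shape[0]
    rng = np.random.default_rng(seed)
    sums = np.zeros(m)
    sq_sums = np.zeros(m)
    base = float(np.mean(predict_fn(background)))
    # evaluate each permutation's M prefix coalitions in one batched call
    chunk = max(1, 4096 // max(1, m * n_bg // 64))
    perms = [rng.permutation(m) for _ in range(n_permutations)]
    for start in range(0, n_permutations, chunk):
        batch = perms[start:start + chunk]
        rows = np.empty((len(batch) * m * n_bg, m))
        pos = 0
        for perm in batch:
            block = background.copy()
            for i in perm:
                block[:, i] = x[i]
                rows[pos:pos + n_bg] = block
                pos += n_bg
        preds = predict_fn(rows).reshape(len(batch), m, n_bg).mean(axis=2)
        for bi, perm in enumerate(batch):
            prev = base
            for k, i in enumerate(perm):
                contrib = preds[bi, k] - prev
                sums[i] += contrib
                sq_sums[i] += contrib * contrib
                prev = preds[bi, k]
    values = sums / n_permutations
    var = sq_sums / n_permutations - values ** 2
    stderr = np.sqrt(np.maximum(var, 0.0) / n_permutations)
    return SampledShap(values=values, stderr=stderr, n_permutations=n_permutations)


def shap_for_dataset(predict_fn, X: np.ndarray, background: np.ndarray,
                     n_permutations: int = 2000, seed: int = 0,
                     exact_if_possible: bool = True) -> np.ndarray:
    """Per-record Shapley values for every row of ``X`` (records x features)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m = X.shape[1]
    out = np.empty_like(X)
    for r, x in enumerate(X):
        if exact_if_possible and m <= EXACT_LIMIT:
            out[r] = shapley_exact(predict_fn, x, background)
        else:
            out[r] = shapley_sampled(predict_fn, x, background,
                                     n_permutations, seed + r).values
    return out


def shap_global(shap_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Global importance (mean |SHAP| per feature) and percent-of-max.

    Percent-of-max is rounded to the nearest integer for reporting; the top
    feature is always 100%.
    """
    shap_values = np.atleast_2d(np.asarray(shap_values, dtype=float))
    if shap_values.shape[0] < 1:
        raise ValueError("need at least one record")
    glob = np.mean(np.abs(shap_values), axis=0)
    top = np.max(glob)
    pct = np.full(glob.shape, 100.0) if top == 0 else 100.0 * glob / top
    return glob, np.round(pct).astype(int)


@dataclass
class RankReport:
    """Ranked feature importances with per-lead/per-family summaries."""

    table: pd.DataFrame
    per_lead: pd.DataFrame
    per_family: pd.DataFrame
    threshold: float
    flagged: list[str] = field(default_factory=list)


def _parse_feature(name: str) -> tuple[str, str | None]:
    """Split a feature name into (family, lead); RR features have no lead."""
    if name.startswith("RRi"):
        return name, None
    family, lead = name.rsplit("_", 1)
    return family, lead


def rank_report(global_importance: np.ndarray, names: list[str],
                threshold_fraction: float = 0.25) -> RankReport:
    """Rank features, flag those above a fraction of the maximum importance,
    and aggregate per lead and per feature family.

    The per-lead summary (mean and min-max over each lead's four PQ
    features) excludes the global RR features, which belong to no lead.
    """
    glob = np.asarray(global_importance, dtype=float)
    _, pct = shap_global(glob[None, :])
    threshold = threshold_fraction * float(np.max(glob))
    table = pd.DataFrame({"feature": names, "importance": glob, "pct_of_max": pct})
    table["flagged"] = table["importance"] > threshold
    table = table.sort_values("importance", ascending=False).reset_index(drop=True)

    parsed = [_parse_feature(n) for n in names]
    lead_rows, family_rows = {}, {}
    for (family, lead), g in zip(parsed, glob):
        if lead is not None:
            lead_rows.setdefault(lead, []).append(g)
            family_rows.setdefault(family, []).append(g)
    per_lead = pd.DataFrame(
        [{"lead": k, "mean": np.mean(v), "min": np.min(v), "max": np.max(v)}
         for k, v in lead_rows.items()]).sort_values("mean", ascending=False)
    per_family = pd.DataFrame(
        [{"family": k, "mean": np.mean(v), "min": np.min(v), "max": np.max(v)}
         for k, v in family_rows.items()]).sort_values("mean", ascending=False)
    flagged = table.loc[table["flagged"], "feature"].tolist()
    return RankReport(table=table, per_lead=per_lead.reset_index(drop=True),
                      per_family=per_family.reset_index(drop=True),
                      threshold=threshold, flagged=flagged)
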