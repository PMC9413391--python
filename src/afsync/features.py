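"""The six AV-synchronization statistics and lead-set feature vectors.

Per record: RRi-mean and RRi-std (global, from the reference-lead R train)
plus, per lead, PQi-mean/PQi-std (ms, P-peak to QRS-onset time) and
PQa-mean/PQa-std (mV, P-peak minus QRS-onset amplitude).  Beats without a
detected P-/f-peak contribute nothing to the PQ statistics — in AF that
exclusion, together with erratic surviving PQ measurements, is exactly the
signal the classifier learns from.  Feature-vector dimension is
2 + 4 x n_leads: 6 (single lead), 26 (limb or chest set), 50 (twelve).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from afsync.delineate import MISSING, FiducialSeries

logger = logging.getLogger(__name__)

LIMB_LEADS = ("I", "II", "III", "aVR", "aVL", "aVF")
CHEST_LEADS = ("V1", "V2", "V3", "V4", "V5", "V6")

#: Named lead sets; a single lead is addressed as e.g. ``single:II``.
LEAD_SETS: dict[str, tuple[str, ...]] = {
    "limb": LIMB_LEADS,
    "chest": CHEST_LEADS,
    "twelve": LIMB_LEADS + CHEST_LEADS,
}


def resolve_lead_set(lead_set: str) -> tuple[str, ...]:
    """Map a lead-set name (``twelve``, ``limb``, ``chest``, ``single:L``)
    to its ordered lead tuple."""
    if lead_set in LEAD_SETS:
        return LEAD_SETS[lead_set]
    if lead_set.startswith("single:"):
        lead = lead_set.split(":", 1)[1]
        if lead in LIMB_LEADS + CHEST_LEADS:
            return (lead,)
    raise ValueError(
        f"unknown lead set {lead_set!r}; expected one of "
        f"{sorted(LEAD_SETS)} or 'single:<lead>'"
    )


def feature_names(lead_set: str) -> list[str]:
    """Fixed feature ordering: RRi pair first, then per lead the PQ quadruple."""
    names = ["RRi_mean", "RRi_std"]
    for lead in resolve_lead_set(lead_set):
        names += [f"PQi_mean_{lead}", f"PQi_std_{lead}",
                  f"PQa_mean_{lead}", f"PQa_std_{lead}"]
    return names


def compute_rr_features(r_idx: np.ndarray, fs: float) -> tuple[float, float]:
    """Mean and sample std (ms) of consecutive R-to-R distances."""
    r_idx = np.asarray(r_idx)
    if r_idx.size < 3:
        raise ValueError(
            f"need >= 3 R fiducials for RR statistics, got {r_idx.size}")
    rr_ms = np.diff(r_idx) * 1000.0 / fs
    return float(np.mean(rr_ms)), float(np.std(rr_ms, ddof=1))


def compute_pq_features(fid: FiducialSeries, lead: str,
                        signal: np.ndarray) -> tuple[float, float, float, float]:
    """PQ interval/amplitude statistics for one lead.

    Beats whose P-/f-peak is MISSING (or whose Q was skipped) are excluded
    from the statistics.  Returns NaNs when no beat has a valid PQ pair and
    std = 0 with a logged warning when only one does.
    """
    q = fid.q_idx[lead]
    p = fid.p_idx[lead]
    valid = (q != MISSING) & (p != MISSING)
    if not np.any(valid):
        return (np.nan, np.nan, np.nan, np.nan)
    qv, pv = q[valid], p[valid]
    pqi = (qv - pv) * 1000.0 / fid.fs
    sig = np.asarray(signal, dtype=float)
    pqa = sig[pv] - sig[qv]
    if valid.sum() == 1:
        logger.warning("lead %s: single valid PQ measurement; std set to 0", lead)
        return float(pqi[0]), 0.0, float(pqa[0]), 0.0
    return (float(np.mean(pqi)), float(np.std(pqi, ddof=1)),
            float(np.mean(pqa)), float(np.std(pqa, ddof=1)))


def assemble_feature_vector(rr: tuple[float, float],
                            per_lead: dict[str, tuple[float, float, float, float]],
                            lead_set: str) -> pd.Series:
    """Assemble the named feature vector for a lead set.

    Dimension is checked against 2 + 4 x n_leads; a required lead missing
    from ``per_lead`` raises.
    """
    leads = resolve_lead_set(lead_set)
    missing = [lead for lead in leads if lead not in per_lead]
    if missing:
        raise ValueError(f"missing leads for lead set {lead_set!r}: {missing}")
    values = [rr[0], rr[1]]
    for lead in leads:
        values.extend(per_lead[lead])
    vec = pd.Series(values, index=feature_names(lead_set), dtype=float)
    assert vec.size == 2 + 4 * len(leads)
    return vec


def extract_features(signals: np.ndarray, leads: tuple[str, ...],
                     fid: FiducialSeries, lead_set: str) -> pd.Series:
    """Compute the full feature vector of one preprocessed record."""
    X = np.atleast_2d(np.asarray(signals, dtype=float))
    rr = compute_rr_features(fid.r_idx, fid.fs)
    per_lead = {}
    for lead in resolve_lead_set(lead_set):
        per_lead[lead] = compute_pq_features(fid, lead, X[leads.index(lead)])
    return assemble_feature_vector(rr, per_lead, lead_set)
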