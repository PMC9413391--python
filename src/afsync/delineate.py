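"""Rule-based delineation of three characteristic points per heart beat.

For each beat we locate:

* the R-wave fiducial, via an adaptive-threshold detector operating on the
  spatial velocity (absolute first derivative summed over leads), with a
  200 ms refractory period and search-back for missed beats;
* the QRS onset (Q), as the first isoelectric (low-slope) sample scanned
  backward from R within 120 ms, with a slope threshold that starts at
  20 uV and is incremented by 1 uV until some sample qualifies;
* the preceding P-/f-peak, as the largest high-slope deflection within
  the physiological window 40-300 ms before Q, using absolute-difference
  criteria at 20/40 ms lags against a fixed 3 uV threshold.  A beat may
  legitimately have no P-/f-peak (MISSING), which is how fibrillatory
  baselines with sub-threshold atrial activity are encoded downstream.

All thresholds are in uV; signals are in mV.  Sample indexing is 0-based
and millisecond windows are converted at the record's sampling rate by
rounding to the nearest sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

#: Sentinel for a beat without a detected P-/f-peak (or skipped Q).
MISSING = -1

REFRACTORY_MS = 200.0
Q_SEARCH_MS = 120.0
P_WINDOW_MS = (300.0, 40.0)  # before Q: [Q-300 ms, Q-40 ms]


@dataclass
class SlopeThresholds:
    """Slope thresholds (uV) for Q-onset and P-peak criteria.

    ``thr_q`` is the starting Q-onset threshold for each beat's scan and
    grows in 1 uV increments until the scan succeeds; ``thr_p`` is fixed.
    """

    thr_q: float = 20.0
    thr_q_increment: float = 1.0
    thr_p: float = 3.0


@dataclass
class FiducialSeries:
    """Per-beat fiducials: shared R indices plus per-lead Q and P indices.

    ``q_idx``/``p_idx`` map lead name -> int array aligned with ``r_idx``;
    entries equal to :data:`MISSING` mark beats without that fiducial.
    """

    r_idx: np.ndarray
    q_idx: dict[str, np.ndarray] = field(default_factory=dict)
    p_idx: dict[str, np.ndarray] = field(default_factory=dict)
    fs: float = 500.0


def _ms(fs: float, ms: float) -> int:
    return int(round(ms * fs / 1000.0))


def detect_qrs(signals: np.ndarray, fs: float) -> np.ndarray:
    """Detect R-wave fiducials from one or more leads.

    Works on the smoothed spatial velocity with three beat-to-beat adaptive
    quantities: a running signal-peak estimate, a running noise-peak
    estimate (together defining the slew-rate/amplitude threshold), and the
    running RR median driving search-back for missed beats after 1.5x the
    median interval.  Detections are refined to the extremum of the summed
    absolute amplitude so they land on the R apex.
    """
    X = np.atleast_2d(np.asarray(signals, dtype=float))
    n = X.shape[1]
    if n < 2 * fs:
        raise ValueError("need at least 2 s of signal for QRS detection")

    velocity = np.abs(np.diff(X, axis=1)).sum(axis=0)
    win = max(1, _ms(fs, 40))
    y = np.convolve(velocity, np.ones(win) / win, mode="same")
    y = np.concatenate([y, [0.0]])[:n]

    if not np.any(y > 0):
        return np.array([], dtype=int)

    cand, _ = find_peaks(y, distance=max(1, _ms(fs, 50)))
    if cand.size == 0:
        return np.array([], dtype=int)

    refractory = _ms(fs, REFRACTORY_MS)
    spk = float(np.max(y[: int(2 * fs)]))
    npk = 0.1 * spk

    def thr() -> float:
        return npk + 0.35 * (spk - npk)

    accepted: list[int] = []
    for p in cand:
        if accepted and p - accepted[-1] < refractory:
            if y[p] > y[accepted[-1]]:
                accepted[-1] = int(p)
            continue
        if y[p] >= thr():
            accepted.append(int(p))
            spk = 0.25 * y[p] + 0.75 * spk
        else:
            npk = 0.25 * y[p] + 0.75 * npk

    # search-back: revisit gaps exceeding 1.5x the running RR median with a
    # halved threshold
    if len(accepted) >= 3:
        rr_med = float(np.median(np.diff(accepted)))
        low_thr = 0.5 * thr()
        inserted = True
        while inserted:
            inserted = False
            gaps = np.diff(accepted)
            for i, g in enumerate(gaps):
                if g > 1.5 * rr_med:
                    lo, hi = accepted[i] + refractory, accepted[i + 1] - refractory
                    inside = cand[(cand >= lo) & (cand <= hi)]
                    if inside.size and np.max(y[inside]) >= low_thr:
                        accepted.insert(i + 1, int(inside[np.argmax(y[inside])]))
                        inserted = True
                        break

    # refine each detection to the nearby amplitude extremum (R apex)
    env = np.abs(X).sum(axis=0)
    half = _ms(fs, 60)
    refined = []
    for p in accepted:
        lo, hi = max(0, p - half), min(n, p + half + 1)
        refined.append(lo + int(np.argmax(env[lo:hi])))
    refined = sorted(set(refined))
    out = [refined[0]] if refined else []
    for r in refined[1:]:
        if r - out[-1] >= refractory:
            out.append(r)
        elif env[r] > env[out[-1]]:
            out[-1] = r
    return np.asarray(out, dtype=int)


def _q_conditions(x: np.ndarray, t: int, lag10: int, lag20: int, thr_mv: float) -> bool:
    """Low-slope (isoelectric) test at sample t.

    The leading condition bounds |x_t - x_{t-tau}| for every lag tau within
    20 ms — a true isoelectric-segment check, which a single endpoint
    difference is not (it passes spuriously wherever a steep wave recrosses
    its level of 10 or 20 ms earlier).  Three endpoint bounds at the
    10/20 ms lags complete the criterion.
    """
    window = np.abs(x[t] - x[t - lag20:t])
    d20 = abs(x[t] - x[t - lag20])
    d10 = abs(x[t] - x[t - lag10])
    d10b = abs(x[t - lag10] - x[t - lag20])
    return (float(np.max(window)) <= thr_mv and d20 <= 4 * thr_mv
            and d10 <= 3 * thr_mv and d10b <= 3 * thr_mv)


def detect_q_onset(signal: np.ndarray, r: int, fs: float,
                   thresholds: SlopeThresholds | None = None,
                   return_threshold: bool = False):
    """Locate the QRS onset as the first isoelectric sample before R.

    Scans t backward from ``r`` over [r - 120 ms, r] and returns the first
    (latest) sample where all four low-slope conditions hold at the current
    threshold; if no sample qualifies the threshold grows by 1 uV and the
    scan repeats, which guarantees termination.  Returns ``None`` (beat
    skipped) when the beat sits too close to the record start to evaluate
    the 20 ms lag.  With ``return_threshold`` the pair (q, thr_q in force)
    is returned so the conditions are assertable post-hoc.
    """
    thresholds = thresholds or SlopeThresholds()
    x = np.asarray(signal, dtype=float)
    lag10, lag20 = max(1, _ms(fs, 10)), max(1, _ms(fs, 20))
    t_min = max(r - _ms(fs, Q_SEARCH_MS), lag20)
    if r < lag20 or t_min > r:
        logger.debug("beat at sample %d skipped: too close to record start", r)
        return (None, None) if return_threshold else None
    thr = thresholds.thr_q
    while True:
        thr_mv = thr / 1000.0
        for t in range(r, t_min - 1, -1):
            if _q_conditions(x, t, lag10, lag20, thr_mv):
                return (t, thr) if return_threshold else t
        thr += thresholds.thr_q_increment
        if thr > 1e7:  # unreachable for finite signals; safety stop
            return (None, None) if return_threshold else None


def detect_p_peak(signal: np.ndarray, q: int, fs: float,
                  thresholds: SlopeThresholds | None = None) -> int | None:
    """Locate the P-/f-peak before a QRS onset, or ``None`` if absent.

    Candidates t in [q - 300 ms, q - 40 ms] must satisfy four
    absolute-difference conditions against the fixed 3 uV threshold
    (polarity-blind, so inverted P-waves qualify):

    |x_t - x_{t-40}| > 4*Thr, |x_t - x_{t+40}| > Thr,
    |x_t - x_{t-20}| > Thr,   |x_t - x_{t+20}| > Thr/2.

    Among qualifying candidates the one with the largest total deflection
    |x_t - x_{t-40}| + |x_t - x_{t+40}| is returned as the peak.
    """
    thresholds = thresholds or SlopeThresholds()
    x = np.asarray(signal, dtype=float)
    lag20, lag40 = max(1, _ms(fs, 20)), max(1, _ms(fs, 40))
    lo = max(q - _ms(fs, P_WINDOW_MS[0]), lag40)
    hi = min(q - _ms(fs, P_WINDOW_MS[1]), x.size - 1 - lag40)
    if hi < lo:
        return None
    t = np.arange(lo, hi + 1)
    d40m = np.abs(x[t] - x[t - lag40])
    d40p = np.abs(x[t] - x[t + lag40])
    d20m = np.abs(x[t] - x[t - lag20])
    d20p = np.abs(x[t] - x[t + lag20])
    thr_mv = thresholds.thr_p / 1000.0
    ok = (d40m > 4 * thr_mv) & (d40p > thr_mv) & (d20m > thr_mv) & (d20p > thr_mv / 2)
    if not np.any(ok):
        return None
    deflection = d40m + d40p
    deflection[~ok] = -np.inf
    return int(t[np.argmax(deflection)])


def delineate_record(signals: np.ndarray, leads: tuple[str, ...], fs: float,
                     reference_lead: str = "I",
                     thresholds: SlopeThresholds | None = None) -> FiducialSeries:
    """Delineate every lead of a preprocessed record.

    R fiducials are detected once on the reference lead (lead I when
    available, else the first lead) and shared across leads; Q onsets and
    P-/f-peaks are lead-specific because AV-synchronization timing and
    amplitude differ per lead.
    """
    X = np.atleast_2d(np.asarray(signals, dtype=float))
    thresholds = thresholds or SlopeThresholds()
    ref = leads.index(reference_lead) if reference_lead in leads else 0
    r_idx = detect_qrs(X[ref], fs)
    fid = FiducialSeries(r_idx=r_idx, fs=fs)
    for li, lead in enumerate(leads):
        q_arr = np.full(r_idx.size, MISSING, dtype=int)
        p_arr = np.full(r_idx.size, MISSING, dtype=int)
        for bi, r in enumerate(r_idx):
            q = detect_q_onset(X[li], int(r), fs, thresholds)
            if q is None:
                continue
            q_arr[bi] = q
            p = detect_p_peak(X[li], q, fs, thresholds)
            if p is not None:
                p_arr[bi] = p
        fid.q_idx[lead] = q_arr
        fid.p_idx[lead] = p_arr
    return fid


def fiducials_to_frame(fid: FiducialSeries, record_id: str = "") -> "pd.DataFrame":
    """Tabulate fiducials as (record_id, lead, beat, r_idx, q_idx, p_idx)."""
    import pandas as pd

    rows = []
    for lead in fid.q_idx:
        for bi, r in enumerate(fid.r_idx):
            q = fid.q_idx[lead][bi]
            p = fid.p_idx[lead][bi]
            rows.append({
                "record_id": record_id, "lead": lead, "beat": bi,
                "r_idx": int(r),
                "q_idx": int(q) if q != MISSING else pd.NA,
                "p_idx": int(p) if p != MISSING else pd.NA,
            })
    return pd.DataFrame(rows)
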