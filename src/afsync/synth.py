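"""Synthetic 12-lead ECG with ground-truth fiducials and rhythm labels.

Sinus records carry a Gaussian P-wave in every beat with the physiological
per-lead polarity pattern (positive in I, II and aVF; negative in aVR;
low-amplitude in aVL and V1), a stable PQ interval (P apex a fixed time
before the QRS onset) and low RR variability.  AF records have no P-waves;
instead a continuous low-amplitude 4-9 Hz fibrillatory oscillation rides
on the baseline, the ventricular response is faster, and the RR intervals
are drawn with a high coefficient of variation from a log-normal
distribution (positive support, right skew - a reasonable stand-in for the
irregular AF ventricular response).

Each beat is a sum of Gaussian bumps (P, Q, R, S, T) whose apex positions
are known analytically, so delineation error statistics against the
generated truth are exact.  Chest leads reuse the limb-lead morphology
with amplitude scaling; realistic precordial progression is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from afsync.ecg_io import STANDARD_LEADS, ClassLabel, EcgRecord

#: Per-lead P-wave polarity/scale (sinus pattern).
P_POLARITY: dict[str, float] = {
    "I": 1.0, "II": 1.0, "III": 0.6, "aVR": -1.0, "aVL": 0.4, "aVF": 1.0,
    "V1": 0.4, "V2": 0.7, "V3": 0.8, "V4": 0.8, "V5": 0.8, "V6": 0.7,
}

#: Per-lead QRS amplitude scale (R-wave sign included).
QRS_SCALE: dict[str, float] = {
    "I": 0.7, "II": 1.0, "III": 0.5, "aVR": -0.8, "aVL": 0.4, "aVF": 0.8,
    "V1": -0.5, "V2": 0.8, "V3": 1.1, "V4": 1.3, "V5": 1.2, "V6": 1.0,
}

#: QRS onset precedes the R apex by this much (ms).
QRS_ONSET_BEFORE_R_MS = 40.0

_MIN_RR_MS = 250.0


@dataclass
class SynthConfig:
    """Generator parameters; defaults describe a clean sinus record."""

    rhythm: str = "SINUS"  # SINUS or AF
    hr_mean: float = 70.0  # bpm
    rr_cv: float = 0.04
    p_amp: float = 0.15  # mV, scaled per lead by P_POLARITY
    pq_interval_ms: float = 160.0  # QRS onset minus P apex
    f_freq_range: tuple[float, float] = (4.0, 9.0)  # Hz
    f_amp: float = 0.0  # mV, fibrillatory-wave amplitude (AF only)
    noise_baseline: float = 0.0  # mV, slow drift amplitude
    noise_mains: float = 0.0  # mV, 50 Hz amplitude
    noise_emg: float = 0.0  # mV RMS, white noise
    duration_s: float = 20.0
    fs: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rhythm not in ("SINUS", "AF"):
            raise ValueError(f"rhythm must be SINUS or AF, got {self.rhythm!r}")
        if self.rhythm == "SINUS" and self.f_amp != 0.0:
            raise ValueError("sinus rhythm must have zero f-wave amplitude")
        if self.rhythm == "AF" and self.p_amp != 0.0:
            raise ValueError("AF must have zero P-wave amplitude")
        if self.rr_cv < 0:
            raise ValueError("rr_cv must be non-negative")


def af_config(**overrides) -> SynthConfig:
    """A SynthConfig with AF defaults: fast irregular rate, f-waves, no P."""
    base = dict(rhythm="AF", hr_mean=120.0, rr_cv=0.25, p_amp=0.0, f_amp=0.06)
    base.update(overrides)
    return SynthConfig(**base)


@dataclass
class GroundTruth:
    """Analytic fiducials of a generated record (P absent for AF)."""

    r_idx: np.ndarray
    q_idx: np.ndarray
    p_idx: np.ndarray | None
    label: ClassLabel = ClassLabel.NON_AF


def _gauss(t_ms: np.ndarray, center_ms: float, sigma_ms: float) -> np.ndarray:
    return np.exp(-0.5 * ((t_ms - center_ms) / sigma_ms) ** 2)


def _draw_rr(rng: np.random.Generator, mean_ms: float, cv: float, n: int) -> np.ndarray:
    """Log-normal RR intervals with given mean and CV, truncated >= 250 ms."""
    if cv <= 0:
        return np.full(n, mean_ms)
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean_ms) - sigma2 / 2.0
    rr = rng.lognormal(mu, np.sqrt(sigma2), size=n)
    return np.maximum(rr, _MIN_RR_MS)


def generate_record(config: SynthConfig, record_id: str = "synth000",
                    patient_id: str = "") -> tuple[EcgRecord, GroundTruth]:
    """Generate one 12-lead record plus its exact fiducials.

    Bit-reproducible for a given config and seed.
    """
    rng = np.random.default_rng(config.seed)
    fs, dur_ms = config.fs, config.duration_s * 1000.0
    n = int(round(config.duration_s * fs))
    t_ms = np.arange(n) * 1000.0 / fs

    mean_rr = 60000.0 / config.hr_mean
    rr = _draw_rr(rng, mean_rr, config.rr_cv, int(dur_ms / _MIN_RR_MS) + 2)
    r_times = 400.0 + rng.uniform(0, 50) + np.concatenate(([0.0], np.cumsum(rr)))
    r_times = r_times[r_times < dur_ms - 200.0]

    onset_times = r_times - QRS_ONSET_BEFORE_R_MS
    p_times = onset_times - config.pq_interval_ms if config.rhythm == "SINUS" else None

    # piecewise-linear QRS (sharp onset and apexes): breakpoints relative to
    # the R apex in ms -> amplitude in mV; Gaussian T wave
    qrs_shape = [(-QRS_ONSET_BEFORE_R_MS, 0.0), (-32.0, -0.15), (0.0, 1.0),
                 (20.0, -0.25), (40.0, 0.0)]
    t_wave = (280.0, 55.0, 0.25)

    signals = np.zeros((len(STANDARD_LEADS), n))
    bp_t = np.concatenate([[0.0]] + [r + np.array([p[0] for p in qrs_shape])
                                     for r in r_times] + [[dur_ms + 1.0]])
    bp_a = np.concatenate([[0.0]] + [np.array([p[1] for p in qrs_shape])
                                     for _ in r_times] + [[0.0]])
    base_beat = np.interp(t_ms, bp_t, bp_a)
    for r in r_times:
        base_beat += t_wave[2] * _gauss(t_ms, r + t_wave[0], t_wave[1])
    p_comp = np.zeros(n)
    if p_times is not None and config.p_amp:
        for p in p_times:
            p_comp += _gauss(t_ms, p, 24.0)

    if config.rhythm == "AF" and config.f_amp > 0:
        f1, f2 = rng.uniform(*config.f_freq_range, size=2)
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        f_wave = 0.5 * config.f_amp * (
            np.sin(2 * np.pi * f1 * t_ms / 1000.0 + ph1)
            + np.sin(2 * np.pi * f2 * t_ms / 1000.0 + ph2))
    else:
        f_wave = np.zeros(n)

    for li, lead in enumerate(STANDARD_LEADS):
        x = QRS_SCALE[lead] * base_beat
        x = x + config.p_amp * P_POLARITY[lead] * p_comp
        x = x + abs(P_POLARITY[lead]) * f_wave
        if config.noise_baseline:
            drift_f = rng.uniform(0.15, 0.4)
            x = x + config.noise_baseline * np.sin(
                2 * np.pi * drift_f * t_ms / 1000.0 + rng.uniform(0, 2 * np.pi))
        if config.noise_mains:
            x = x + config.noise_mains * np.sin(2 * np.pi * 50.0 * t_ms / 1000.0)
        if config.noise_emg:
            x = x + rng.normal(0.0, config.noise_emg, n)
        signals[li] = x

    to_idx = lambda times: np.round(times * fs / 1000.0).astype(int)
    truth = GroundTruth(
        r_idx=to_idx(r_times),
        q_idx=to_idx(onset_times),
        p_idx=to_idx(p_times) if p_times is not None else None,
        label=ClassLabel.AF if config.rhythm == "AF" else ClassLabel.NON_AF,
    )
    codes = frozenset({"164889003"}) if config.rhythm == "AF" else frozenset({"426783006"})
    rec = EcgRecord(record_id, signals, STANDARD_LEADS, fs, codes,
                    patient_id or record_id)
    return rec, truth


def generate_dataset(n_records: int, af_fraction: float = 0.08, seed: int = 0,
                     duration_s: float = 20.0, fs: float = 500.0,
                     noise: bool = True
                     ) -> tuple[list[tuple[EcgRecord, GroundTruth]], pd.DataFrame]:
    """Generate a labelled dataset with randomized per-record physiology.

    The AF share is round(n x af_fraction).  Sinus heart rates span
    55-90 bpm with RR CV 0.02-0.06; AF rates span 95-150 bpm with RR CV
    0.15-0.30 and f-wave amplitudes 0.02-0.1 mV.  Mild baseline/EMG noise
    is added unless ``noise`` is False.  Every record gets a distinct
    synthetic patient id, and a manifest table is returned alongside.
    """
    if not 0.0 < af_fraction < 1.0:
        raise ValueError("af_fraction must lie in (0, 1)")
    master = np.random.default_rng(seed)
    n_af = int(round(n_records * af_fraction))
    is_af = np.zeros(n_records, dtype=bool)
    is_af[master.choice(n_records, size=n_af, replace=False)] = True

    out, rows = [], []
    for i in range(n_records):
        sub_seed = int(master.integers(0, 2 ** 31 - 1))
        r = np.random.default_rng(sub_seed)
        common = dict(
            duration_s=duration_s, fs=fs, seed=sub_seed,
            noise_baseline=float(r.uniform(0.02, 0.06)) if noise else 0.0,
            noise_emg=float(r.uniform(0.002, 0.008)) if noise else 0.0,
        )
        if is_af[i]:
            cfg = af_config(hr_mean=float(r.uniform(95, 150)),
                            rr_cv=float(r.uniform(0.15, 0.30)),
                            f_amp=float(r.uniform(0.02, 0.10)), **common)
        else:
            cfg = SynthConfig(hr_mean=float(r.uniform(55, 90)),
                              rr_cv=float(r.uniform(0.02, 0.06)),
                              p_amp=float(r.uniform(0.10, 0.20)),
                              pq_interval_ms=float(r.uniform(140, 180)), **common)
        rid, pid = f"synth{i:04d}", f"pt{i:04d}"
        rec, truth = generate_record(cfg, record_id=rid, patient_id=pid)
        out.append((rec, truth))
        rows.append({"record_id": rid, "patient_id": pid,
                     "label": truth.label.value, "rhythm": cfg.rhythm,
                     "hr_mean": cfg.hr_mean, "rr_cv": cfg.rr_cv, "seed": sub_seed})
    return out, pd.DataFrame(rows)
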