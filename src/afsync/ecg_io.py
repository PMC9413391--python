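"""Reading, labeling and splitting multi-lead ECG records.

Records are exchanged in WFDB format: a plain-text header (``<rec>.hea``)
describing the signal file, plus a 16-bit little-endian binary signal file
(``<rec>.dat``).  Diagnoses travel as SNOMED-CT codes on a ``Dx:`` comment
line of the header (the CinC-2021 convention); unknown comment lines are
ignored.  Only this dialect subset is implemented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

logger = logging.getLogger(__name__)

#: Canonical 12-lead ordering.
STANDARD_LEADS = ("I", "II", "III", "aVR", "aVL", "aVF",
                  "V1", "V2", "V3", "V4", "V5", "V6")

#: SNOMED-CT codes defining the AF class (atrial fibrillation, atrial flutter).
AF_CODES = frozenset({"164889003", "164890007"})

#: SNOMED-CT codes excluding a record (poor R-wave progression, low QRS
#: voltages, pacing rhythm).
EXCLUSION_CODES = frozenset({"365413008", "251146004", "10370003"})

MIN_DURATION_S = 5.0
MAX_DURATION_S = 144.0


class ClassLabel(Enum):
    """Rhythm class of a record; EXCLUDED records never enter any subset."""

    AF = "AF"
    NON_AF = "NON_AF"
    EXCLUDED = "EXCLUDED"


@dataclass
class EcgRecord:
    """A multi-lead ECG record with amplitudes in mV.

    ``signals`` has shape (n_leads, n_samples); ``leads`` names each row
    using the standard lead identifiers.
    """

    record_id: str
    signals: np.ndarray
    leads: tuple[str, ...]
    fs: float
    codes: frozenset[str] = frozenset()
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.signals.shape[0] != len(self.leads):
            raise ValueError(
                f"{self.signals.shape[0]} signal rows for {len(self.leads)} leads"
            )
        if not self.patient_id:
            self.patient_id = self.record_id

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        """Return the signal of one lead by name."""
        try:
            return self.signals[self.leads.index(name)]
        except ValueError as exc:
            raise KeyError(f"lead {name!r} not present in record {self.record_id}") from exc


@dataclass
class DatasetSplit:
    """Patient-wise disjoint train/validation/test record-id lists."""

    train: list[str]
    validation: list[str]
    test: list[str]
    seed: int = 0

    def subsets(self) -> dict[str, list[str]]:
        return {"train": self.train, "validation": self.validation, "test": self.test}


def map_codes_to_class(codes: set[str] | frozenset[str]) -> ClassLabel:
    """Map a record's SNOMED-CT code set to its rhythm class.

    An empty code set or any exclusion code (poor R-wave progression, low
    QRS voltages, pacing rhythm) excludes the record; exclusion takes
    precedence over AF membership.  Otherwise the presence of the AFIB or
    AFL code assigns AF, and anything else is non-AF.
    """
    codes = set(codes)
    if not codes or codes & EXCLUSION_CODES:
        return ClassLabel.EXCLUDED
    if codes & AF_CODES:
        return ClassLabel.AF
    return ClassLabel.NON_AF


def resample_record(rec: EcgRecord, target_fs: float = 500.0) -> EcgRecord:
    """Resample every lead to ``target_fs`` with a polyphase FIR filter.

    Polyphase resampling preserves waveform morphology (and hence the
    slope criteria used downstream) better than linear interpolation.
    Duration is preserved to within one sample period.
    """
    if rec.n_samples == 0:
        raise ValueError("cannot resample an empty record")
    if rec.fs <= 0:
        raise ValueError("sampling frequency must be positive")
    if rec.fs == target_fs:
        return rec
    ratio = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = resample_poly(rec.signals, ratio.numerator, ratio.denominator, axis=1)
    return EcgRecord(rec.record_id, out, rec.leads, float(target_fs),
                     rec.codes, rec.patient_id)


def validate_record(rec: EcgRecord) -> bool:
    """True if the record duration lies in the accepted 5-144 s range."""
    ok = MIN_DURATION_S <= rec.duration_s <= MAX_DURATION_S
    if not ok:
        logger.warning("record %s rejected: duration %.2f s outside [%g, %g] s",
                       rec.record_id, rec.duration_s, MIN_DURATION_S, MAX_DURATION_S)
    return ok


# ---------------------------------------------------------------------------
# WFDB dialect I/O (header + 16-bit signal file)
# ---------------------------------------------------------------------------

_WFDB_GAIN = 1000.0  # ADC units per mV
_WFDB_FMT = "16"


def write_wfdb(rec: EcgRecord, directory: str | Path) -> Path:
    """Write ``<rec>.hea`` and 16-bit ``<rec>.dat`` files; returns header path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dat_name = f"{rec.record_id}.dat"
    adc = np.round(rec.signals * _WFDB_GAIN).astype("<i2")
    # sample-interleaved layout, as WFDB format 16 prescribes
    adc.T.tofile(directory / dat_name)
    lines = [f"{rec.record_id} {len(rec.leads)} {rec.fs:g} {rec.n_samples}"]
    for i, lead in enumerate(rec.leads):
        first = int(adc[i, 0]) if rec.n_samples else 0
        lines.append(
            f"{dat_name} {_WFDB_FMT} {_WFDB_GAIN:g}/mV 16 0 {first} 0 0 {lead}"
        )
    lines.append(f"#Dx: {','.join(sorted(rec.codes))}")
    lines.append(f"#Patient: {rec.patient_id}")
    hea = directory / f"{rec.record_id}.hea"
    hea.write_text("\n".join(lines) + "\n")
    return hea


def read_wfdb(header_path: str | Path) -> EcgRecord:
    """Read one record from its ``.hea`` header and 16-bit ``.dat`` file."""
    header_path = Path(header_path)
    lines = [ln.strip() for ln in header_path.read_text().splitlines() if ln.strip()]
    rec_fields = lines[0].split()
    record_id, n_sig = rec_fields[0], int(rec_fields[1])
    fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    n_samples = int(rec_fields[3]) if len(rec_fields) > 3 else 0
    leads: list[str] = []
    gains: list[float] = []
    dat_name = None
    for ln in lines[1:1 + n_sig]:
        parts = ln.split()
        dat_name = parts[0]
        gain_str = parts[2].split("/")[0].split("(")[0]
        gains.append(float(gain_str) if float(gain_str) != 0 else _WFDB_GAIN)
        leads.append(parts[-1])
    codes: frozenset[str] = frozenset()
    patient_id = ""
    for ln in lines[1 + n_sig:]:
        if not ln.startswith("#"):
            continue
        body = ln.lstrip("#").strip()
        if body.lower().startswith("dx:"):
            codes = frozenset(c.strip() for c in body[3:].split(",") if c.strip())
        elif body.lower().startswith("patient:"):
            patient_id = body[len("patient:"):].strip()
    raw = np.fromfile(header_path.with_name(dat_name), dtype="<i2")
    adc = raw.reshape(-1, n_sig).T.astype(float)
    if n_samples and adc.shape[1] != n_samples:
        adc = adc[:, :n_samples]
    signals = adc / np.asarray(gains)[:, None]
    return EcgRecord(record_id, signals, tuple(leads), fs, codes, patient_id)


def scan_directory(data_dir: str | Path, target_fs: float = 500.0,
                   validate: bool = True) -> list[EcgRecord]:
    """Load every ``.hea``/``.dat`` pair under ``data_dir``, resampled to
    ``target_fs``; records outside the 5-144 s duration range are dropped
    with a logged warning."""
    records = []
    for hea in sorted(Path(data_dir).glob("*.hea")):
        rec = resample_record(read_wfdb(hea), target_fs)
        if validate and not validate_record(rec):
            continue
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Patient-wise stratified partitioning
# ---------------------------------------------------------------------------

def partition_dataset(
    records: list[tuple[str, str, ClassLabel]],
    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    """Randomly allocate records patient-wise into train/validation/test.

    Stratification is by class at the patient level so the AF prevalence of
    each subset tracks the overall prevalence; a patient with mixed labels
    is stratified by their majority label.  Deterministic given ``seed``.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    for _, _, lab in records:
        if lab == ClassLabel.EXCLUDED:
            raise ValueError("EXCLUDED records may not enter a dataset split")

    by_patient: dict[str, list[tuple[str, ClassLabel]]] = {}
    for rid, pid, lab in records:
        by_patient.setdefault(pid, []).append((rid, lab))

    def majority(recs: list[tuple[str, ClassLabel]]) -> ClassLabel:
        n_af = sum(1 for _, lb in recs if lb == ClassLabel.AF)
        return ClassLabel.AF if 2 * n_af >= len(recs) else ClassLabel.NON_AF

    rng = np.random.default_rng(seed)
    subsets: dict[str, list[str]] = {"train": [], "validation": [], "test": []}
    names = ("train", "validation", "test")
    for cls in (ClassLabel.AF, ClassLabel.NON_AF):
        patients = sorted(p for p, recs in by_patient.items() if majority(recs) == cls)
        rng.shuffle(patients)
        total = sum(len(by_patient[p]) for p in patients)
        # greedy fill: send each patient block to the subset lagging most
        # behind its target record count
        counts = [0, 0, 0]
        for p in patients:
            deficits = [fractions[i] * total - counts[i] for i in range(3)]
            k = int(np.argmax(deficits))
            counts[k] += len(by_patient[p])
            subsets[names[k]].extend(rid for rid, _ in by_patient[p])
    return DatasetSplit(subsets["train"], subsets["validation"], subsets["test"], seed)


def split_manifest(records: list[tuple[str, str, ClassLabel]],
                   split: DatasetSplit) -> pd.DataFrame:
    """Tabulate a split as (record_id, patient_id, label, subset)."""
    subset_of = {rid: name for name, rids in split.subsets().items() for rid in rids}
    rows = [
        {"record_id": rid, "patient_id": pid, "label": lab.value,
         "subset": subset_of.get(rid, "")}
        for rid, pid, lab in records
    ]
    return pd.DataFrame(rows)
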