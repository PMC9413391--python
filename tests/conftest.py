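import numpy as np
import pytest

from afsync.delineate import delineate_record
from afsync.preprocess import preprocess_record
from afsync.synth import SynthConfig, af_config, generate_record

FS = 500.0


@pytest.fixture(scope="session")
def sinus_case():
    """Noise-free sinus record, preprocessed and delineated, with truth."""
    rec, truth = generate_record(SynthConfig(seed=11, duration_s=20.0))
    sig = preprocess_record(rec.signals, rec.fs)
    fid = delineate_record(sig, rec.leads, rec.fs)
    return rec, truth, sig, fid


@pytest.fixture(scope="session")
def af_case():
    """Noise-free AF record (fast irregular rhythm, f-waves, no P)."""
    rec, truth = generate_record(af_config(seed=12, duration_s=20.0))
    sig = preprocess_record(rec.signals, rec.fs)
    fid = delineate_record(sig, rec.leads, rec.fs)
    return rec, truth, sig, fid


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
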