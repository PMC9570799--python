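import numpy as np
import pytest

from pulsewave import (
    SUBJECT1_PPG_R_MORPHOLOGY,
    SynthConfig,
    generate_recording,
    preprocess_recording,
)


def clean_config(n_beats=40, mean_rr=1.0, seed=1, **kw):
    """Noise-free, modulation-free generator config for recovery tests."""
    defaults = dict(
        n_beats=n_beats,
        mean_rr=mean_rr,
        rr_sd=0.0,
        pat_sd=0.0,
        baseline_amp=0.0,
        am_depth=0.0,
        noise_sd=0.0,
        seed=seed,
    )
    defaults.update(kw)
    return SynthConfig(**defaults)


@pytest.fixture(scope="session")
def clean_recording():
    """40 noise-free beats at 60 bpm, subject-1-like morphology."""
    return generate_recording(clean_config())


@pytest.fixture(scope="session")
def clean_preprocessed(clean_recording):
    rec, truth = clean_recording
    return preprocess_recording(rec), truth


@pytest.fixture(scope="session")
def realistic_recording():
    """40 beats with respiratory modulation and mild noise (defaults)."""
    return generate_recording(SynthConfig(n_beats=40, seed=7))


def complete_pairs(detected, truth_sets):
    """Match detected to ground-truth fiducials on complete beats."""
    det = {f.beat_index: f for f in detected if f.quality_flag != "partial"}
    return [(det[t.beat_index], t) for t in truth_sets
            if t.quality_flag != "partial" and t.beat_index in det]
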