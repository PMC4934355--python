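"""Shared fixtures: small synthetic recordings and the session-wide
severity corpus used by the end-to-end tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import pronosup as p


@pytest.fixture(scope="session")
def rec_class0():
    """One healthy-performance recording with default sensor noise."""
    return p.generate(p.severity_to_params(0, 42), 0)


@pytest.fixture(scope="session")
def rec_class0_noiseless():
    from dataclasses import replace
    params = replace(p.severity_to_params(0, 42),
                     noise_accel_g=0.0, noise_gyro_dps=0.0, noise_mag_ut=0.0)
    return p.generate(params, 0)


@pytest.fixture(scope="session")
def processed_class0(rec_class0):
    return p.process_recording(rec_class0.recording)


def _corpus_frames(per_class: int, seed: int):
    """Generate and fully process a severity corpus, keeping only summary
    frames (the raw recordings are too large to hold)."""
    rng = np.random.default_rng(seed)
    rows, bounds = [], []
    for c in range(5):
        for r in range(per_class):
            child = int(rng.integers(0, 2**31 - 1))
            rec = p.generate(p.severity_to_params(c, child), c)
            proc = p.process_recording(rec.recording)
            row = {"recording_id": f"c{c}_r{r:03d}", "label": c}
            row.update(proc.features.as_dict())
            rows.append(row)
            tt = rec.truth_quat.t
            for lab in p.PHASES:
                s1, _ = proc.segmentation[lab]
                s2, _ = rec.truth_phases[lab]
                bounds.append({"label": lab, "class": c,
                               "err_s": abs(tt[s1] - tt[s2])})
    return pd.DataFrame(rows), pd.DataFrame(bounds)


@pytest.fixture(scope="session")
def severity_corpus():
    """5 classes x 100 recordings, processed end to end (features + phase
    boundary errors).  Computed once per session."""
    features, boundaries = _corpus_frames(per_class=100, seed=2025)
    return {"features": features, "boundaries": boundaries}


@pytest.fixture()
def sine_ps():
    """A clean sinusoidal PS phase: amplitude 300 °/s, 1.5 Hz, 10 s."""
    t = np.arange(0, 10, 0.01)
    return 300.0 * np.sin(2 * np.pi * 1.5 * t), t
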