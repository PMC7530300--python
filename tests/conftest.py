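"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tvv.ecg_io import AnnotatedEcg, BeatAnnotation
from tvv.synthetic import BeatMorphology, simulate_ecg, study_a_table


@pytest.fixture(scope="session")
def morph() -> BeatMorphology:
    return BeatMorphology()


@pytest.fixture(scope="session")
def clean_ecg(morph):
    """Noise-free 10-s record plus its designed Tr(p) ground truth."""
    ecg, tr_true = simulate_ecg(morph, rr_s=1.0, rng=np.random.default_rng(7))
    return ecg, tr_true


@pytest.fixture(scope="session")
def study_a_small():
    """10-subject quantile-level study A dataset (table, pk, truth)."""
    return study_a_table(n_subjects=10, seed=11)


@pytest.fixture()
def flat_ecg():
    """Synthetic record with an analytically trivial structure: every lead
    zero in the PQ windows, beats every second."""
    fs = 500.0
    n = 5000
    rng = np.random.default_rng(0)
    sig = rng.normal(0.0, 0.2, size=(n, 8))
    beats = []
    for k in range(9):
        q = 300 + k * 500
        beats.append(BeatAnnotation(q - 60, q, q + 80, q + 240))
        sig[q - 25:q - 3, :] = 0.0  # PQ window (40..10 ms before q) is clean
    return AnnotatedEcg(sig, fs, beats)


def oracle_quantiles(pts: np.ndarray, fs: float) -> np.ndarray:
    """Brute-force cumulative-arc-length quantile oracle (independent of the
    implementation: explicit per-p search plus interpolation)."""
    d = np.sqrt((np.diff(pts, axis=0) ** 2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(d)])
    total = cum[-1]
    out = []
    for p in range(1, 101):
        target = p / 100.0 * total
        i = int(np.searchsorted(cum, target))
        if i == 0:
            out.append(0.0)
            continue
        c0, c1 = cum[i - 1], cum[i]
        frac = 0.0 if c1 == c0 else (target - c0) / (c1 - c0)
        out.append(((i - 1) + frac) / fs * 1000.0)
    return np.array(out)


@pytest.fixture(scope="session")
def rw_trajectories():
    """Random-walk trajectories for oracle-equivalence checks."""
    rng = np.random.default_rng(123)
    trajs = []
    for _ in range(100):
        n = rng.integers(20, 200)
        pts = np.cumsum(rng.normal(0.0, 0.05, size=(n, 3)), axis=0)
        trajs.append(pts)
    return trajs
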