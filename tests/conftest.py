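from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from facetouch.features import FEATURE_NAMES
from facetouch.ingest import align_and_trim
from facetouch.labels import ACTIVITIES
from facetouch.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A short protocol (3 participants × 40 s activities) for unit tests."""
    return SimulationConfig(n_participants=3, activity_duration=40.0,
                            idle_gap=2.0, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_segments(small_cfg, small_dataset):
    recordings, logs = small_dataset
    segs = []
    for rec, log in zip(recordings, logs):
        segs.extend(align_and_trim(rec, log, small_cfg.trim_front,
                                   small_cfg.trim_back))
    return segs


def make_synthetic_matrix(n_participants=10, windows_per_activity=6, seed=0,
                          informative=("mangle", "sdangle"), noise_sd=1.0,
                          separation=4.0) -> pd.DataFrame:
    """A feature matrix of pure noise except for chosen informative columns,
    which are shifted by `separation` for FT windows."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        pid = f"P{i + 1:02d}"
        for act in ACTIVITIES:
            for w in range(windows_per_activity):
                row = {"participant_id": pid, "activity": act.name,
                       "category": act.category,
                       "window_start_s": float(w)}
                for name in FEATURE_NAMES:
                    val = rng.normal(0.0, noise_sd)
                    if name in informative and act.category == "FT":
                        val += separation
                    row[name] = val
                rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture()
def synthetic_matrix():
    return make_synthetic_matrix()
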