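"""Shared fixtures and the scaled end-to-end runner.

End-to-end suites run the pipeline on synthetic seizures at reduced
problem sizes (2-3 h pre-onset windows, 8 channels, a 3 x 3 embedding
grid, univariate-linear features) so the whole suite stays within a
desktop time budget while keeping the study's effect sizes, preictal
geometry and window grid.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from preictal_scout import (PipelineConfig, SeizureEvent, SeizureRoster,
                            run_seizure)
from preictal_scout.embedding import EmbeddingConfig
from preictal_scout.synthetic import SynthConfig, generate_recording

warnings.filterwarnings("ignore", module="umap")
warnings.filterwarnings("ignore", category=FutureWarning)

SMALL_GRID = EmbeddingConfig(n_neighbors_grid=(10, 55, 100),
                             min_dist_grid=(0.1, 0.5, 0.9))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def run_synthetic_seizure(synth_cfg: SynthConfig, seed: int,
                          sleepwake: bool = False,
                          feature_groups=("univariate_linear",)) -> tuple:
    """Generate one synthetic seizure and run the scaled pipeline on it.

    Returns ``(report, ground_truth)``.
    """
    record, truth = generate_recording(synth_cfg)
    roster = SeizureRoster([SeizureEvent(1, record.end_time,
                                         record.end_time + 60.0)])
    config = PipelineConfig(
        feature_groups=feature_groups,
        embedding=SMALL_GRID,
        max_hours=synth_cfg.window_hours,
    ).seeded(seed)
    sw = None
    if sleepwake:
        n_win = truth.sleepwake_vector.size
        sw_times = -(n_win - np.arange(n_win)) * 5.0
        sw = (truth.sleepwake_vector, sw_times)
    report = run_seizure(record, roster, config, sleepwake=sw)
    return report, truth


@pytest.fixture(scope="session")
def recovery_reports():
    """Six scaled seizures with a strong injected preictal regime
    (effect 3 z, start 45 min, duration 20 min, density 1)."""
    out = []
    for i in range(6):
        cfg = SynthConfig(n_channels=8, window_hours=2.0,
                          preictal_start=45.0, preictal_duration=20.0,
                          preictal_density=1.0, effect_size=3.0,
                          rng_seed=100 + i)
        out.append(run_synthetic_seizure(cfg, seed=100 + i))
    return out


@pytest.fixture(scope="session")
def null_reports():
    """Six stationary seizures: no preictal effect, no sleep-wake."""
    out = []
    for i in range(6):
        cfg = SynthConfig(n_channels=8, window_hours=2.0, effect_size=0.0,
                          rng_seed=200 + i)
        out.append(run_synthetic_seizure(cfg, seed=200 + i))
    return out


@pytest.fixture(scope="session")
def sleepwake_reports():
    """Six seizures driven only by 90-min sleep-wake modulation (2 z)."""
    out = []
    for i in range(6):
        cfg = SynthConfig(n_channels=8, window_hours=3.0, effect_size=0.0,
                          sleepwake_period=90.0, sleepwake_effect=2.0,
                          rng_seed=300 + i)
        out.append(run_synthetic_seizure(cfg, seed=300 + i, sleepwake=True))
    return out
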