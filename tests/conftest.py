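"""Shared fixtures: small synthetic datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import lmmcbp as L


@pytest.fixture(scope="session")
def layout8():
    return L.make_layout(8)


@pytest.fixture(scope="session")
def adj8(layout8):
    thr = L.suggest_distance_threshold(layout8)
    return L.build_adjacency(layout8, "distance", distance_threshold=thr)


@pytest.fixture(scope="session")
def small_truth(layout8):
    # 8 electrodes x 12 samples, -100..450 ms at 50 ms spacing
    return L.default_truth(layout8, n_times=12, dt_ms=50.0)


@pytest.fixture(scope="session")
def small_corpus():
    return L.simulate_corpus(
        n_memory=6,
        n_common=8,
        seed=11,
        repeated_word_fraction=0.4,
        n_repeated_pool=18,
    )


@pytest.fixture(scope="session")
def small_dataset(small_corpus, small_truth, layout8):
    """Baseline-corrected, word-filtered epochs + aligned covariates."""
    epochs, table = L.simulate_epochs(
        small_corpus, small_truth, n_subjects=5, layout=layout8, seed=12
    )
    epochs = L.baseline_correct(epochs)
    epochs, table, _ = L.reject_epochs(epochs, table)
    return L.apply_word_filter(epochs, table)


@pytest.fixture(scope="session")
def small_stats(small_dataset):
    epochs, table = small_dataset
    return L.fit_grid(epochs, table, L.ModelSpec())


def make_epochs(amplitudes, t0=-100.0, dt=50.0):
    """Tiny EpochSet factory for hand-built fixtures."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    n_tr, n_el, n_ti = amplitudes.shape
    return L.EpochSet(
        amplitudes=amplitudes,
        times=t0 + dt * np.arange(n_ti),
        electrodes=[f"E{i + 1:02d}" for i in range(n_el)],
        trial_ids=np.arange(n_tr),
    )
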