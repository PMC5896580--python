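"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from cytoevo.trajectory import Trajectory


def trajectory_from_counts(
    counts_list,
    min_kappa=None,
    mean_alpha=None,
    mean_kappa=None,
    stop_reason="max_generations",
    truncated=False,
):
    """Build a synthetic trajectory from per-generation beneficial class counts.

    ``counts_list`` is a list of 1-D genome-count arrays indexed by alpha.
    Summary columns not derivable from the counts can be supplied directly.
    """
    counts = [np.asarray(c, dtype=np.int64) for c in counts_list]
    T = len(counts)
    totals = np.array([c.sum() for c in counts], dtype=np.float64)
    alphas = [np.nonzero(c)[0] for c in counts]
    min_alpha = np.array([a[0] for a in alphas], dtype=np.int64)
    n_classes = np.array([len(a) for a in alphas], dtype=np.int64)
    if mean_alpha is None:
        mean_alpha = np.array(
            [(np.arange(len(c)) * c).sum() / t for c, t in zip(counts, totals)]
        )
    return Trajectory(
        engine="synthetic",
        config={},
        seed=0,
        generation=np.arange(T, dtype=np.int64),
        mean_alpha=np.asarray(mean_alpha, dtype=np.float64),
        mean_kappa=np.zeros(T) if mean_kappa is None else np.asarray(mean_kappa, float),
        min_alpha=min_alpha,
        min_kappa=(
            np.zeros(T, dtype=np.int64)
            if min_kappa is None
            else np.asarray(min_kappa, dtype=np.int64)
        ),
        within_cell_variance=np.zeros(T),
        between_cell_fitness_variance=np.zeros(T),
        n_classes=n_classes,
        alpha_class_counts=counts,
        stop_reason=stop_reason,
        truncated=truncated,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
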