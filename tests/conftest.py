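"""Shared fixtures.

The expensive fixtures (full simulate-and-analyze sweeps) are session-scoped
so the recovery-style tests share one set of pipeline runs.
"""

from __future__ import annotations

import datetime

import numpy as np
import pytest

import hookqc as hq


def make_chip(n_sets: int = 3, probes_per_set: int = 3, with_mm: bool = True,
              sample_id: str = "toy", pm_base: float = 100.0) -> hq.ChipData:
    """Small handmade chip with deterministic pseudo-random sequences."""
    rng = np.random.default_rng(42)
    n = n_sets * probes_per_set
    codes = rng.integers(0, 4, size=(n, 25), dtype=np.uint8)
    from hookqc.io import decode_sequences
    return hq.ChipData(
        sample_id=sample_id,
        probe_id=np.array([f"p{i}" for i in range(n)], dtype=object),
        probeset_id=np.array([f"s{i // probes_per_set}" for i in range(n)],
                             dtype=object),
        probe_index=np.tile(np.arange(1, probes_per_set + 1), n_sets),
        sequence=decode_sequences(codes),
        pm=pm_base + np.arange(n, dtype=float),
        mm=(0.5 * (pm_base + np.arange(n, dtype=float))) if with_mm else None,
    )


@pytest.fixture
def tiny_chip() -> hq.ChipData:
    return make_chip()


@pytest.fixture
def metadata_rows() -> list[hq.SampleMetadata]:
    return [
        hq.SampleMetadata("s1", "E1", datetime.date(2004, 3, 15), "included"),
        hq.SampleMetadata("s2", "E1", datetime.date(2004, 4, 2), "excluded"),
        hq.SampleMetadata("s3", "E2", datetime.date(2005, 3, 15)),
    ]


@pytest.fixture(scope="session")
def default_runs() -> list[tuple[hq.ChipData, hq.GroundTruth,
                                 hq.ChipAnalysis]]:
    """Ten seed-swept default simulations, fully analyzed (artifacts off)."""
    runs = []
    for seed in range(1, 11):
        chip, truth, _ = hq.simulate_chip(hq.SimulationConfig(seed=seed))
        runs.append((chip, truth, hq.analyze_chip(chip)))
    return runs


@pytest.fixture(scope="session")
def ggg_runs() -> list[tuple[hq.GroundTruth, hq.QualityMetrics]]:
    """Ten seed-swept simulations with an injected guanine bias of 0.2."""
    runs = []
    for seed in range(1, 11):
        chip, truth, _ = hq.simulate_chip(
            hq.SimulationConfig(seed=seed, delta_ggg_true=0.2))
        runs.append((truth, hq.compute_qc(chip)))
    return runs


def analyze_cohort(layout_seed: int, gamma_b: float, n_per_batch: int = 20):
    """Simulate and analyze a 2-batch cohort (batch B optionally degraded);
    returns (metric table, batch labeling, PC scores)."""
    from hookqc.batch import (derive_batch_labels,
                              expression_matrix_from_estimates,
                              metrics_to_table, pc_scores)
    base = hq.SimulationConfig(n_sets=1200, probes_per_set=11)
    cohort = hq.CohortConfig(base=base, layout_seed=layout_seed, batches=[
        hq.BatchSpec("A", n_per_batch, {}),
        hq.BatchSpec("B", n_per_batch, {"gamma_decay": gamma_b}),
    ])
    chips, meta, _ = hq.simulate_cohort(cohort)
    analyses = [hq.analyze_chip(c) for c in chips]
    table = metrics_to_table([a.metrics for a in analyses])
    matrix = expression_matrix_from_estimates(
        [(c.sample_id, a.estimates) for c, a in zip(chips, analyses)])
    return table, derive_batch_labels(meta), pc_scores(matrix)
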