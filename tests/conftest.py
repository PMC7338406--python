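"""Shared fixtures.

Unit tests use a small, fast fixture pair; the full-size 20-fixture benchmark
(and the exactness fixtures) are session-scoped and built lazily, so only the
tests that need them pay their cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from skie.core import PipelineConfig, Window
from skie.hotspot import brute_force_max_score
from skie.pipeline import analyze_pair, run_same_field
from skie.registration import SimilarityTransform
from skie.synthetic import FixtureSpec, benchmark_specs, exactness_spec, generate_pair


def small_spec(seed: int = 0, **overrides) -> FixtureSpec:
    """A quarter-size fixture for fast unit tests: 800 px image, 400 px
    (200 um) hot-spot window, same densities as the benchmark."""
    defaults = dict(
        size_px=800,
        blob_center=(400.0, 400.0),
        blob_axes=(260.0, 280.0),
        tissue_axes=(352.0, 368.0),
        hotspot_origin=(200, 200),
        hotspot_side_px=400,
        n_distractor_positives=10,
        transform=SimilarityTransform(scale=1.01, rotation=0.03, tx=8.0, ty=-6.0),
        seed=seed,
    )
    defaults.update(overrides)
    return FixtureSpec(**defaults)


@pytest.fixture(scope="session")
def small_pair():
    """(he, ds, ss, truth) for the default small fixture."""
    return generate_pair(small_spec(0))


@pytest.fixture(scope="session")
def small_pair_identity():
    """Small fixture with identity misalignment: the H&E frame coincides with
    the DS frame, so truth coordinates apply to the H&E image directly."""
    return generate_pair(small_spec(1, transform=SimilarityTransform.identity()))


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    """Config matching the small fixture's 200-um hot-spot windows."""
    return PipelineConfig(hotspot_side_um=200.0, min_tumor_cells=100)


@dataclass
class BenchRecord:
    seed: int
    planted_window: Window
    chosen_window: Window | None
    rank1_score: int | None
    brute_force_max: int | None
    N_est: int
    D_est: int
    N_true: int  # truth in the chosen window
    D_true: int
    index_est: float
    grade_est: str
    true_index_planted: float
    grade_true: str
    valid: bool


def run_benchmark_fixture(seed: int, config: PipelineConfig | None = None) -> BenchRecord:
    cfg = config or PipelineConfig()
    he, ds, ss, truth = generate_pair(FixtureSpec(seed=seed))
    run = analyze_pair(he, ds, truth.landmarks_he, truth.landmarks_ds, cfg)
    r = run.result
    assert r is not None, f"benchmark fixture {seed}: no result"
    n_true, d_true = truth.truth_counts(r.window)
    n_p, d_p = truth.truth_counts(truth.hotspot_window)
    window_px = cfg.hotspot_side_px(ds.mpp)
    bf = brute_force_max_score(
        run.ki67_in_tumor_mask, ds.shape, window_px, stride=window_px // cfg.hotspot_stride_divisor
    )
    true_index = 100.0 * n_p / d_p
    from skie.grading import assign_grade

    return BenchRecord(
        seed=seed,
        planted_window=truth.hotspot_window,
        chosen_window=r.window,
        rank1_score=run.candidates[0].score,
        brute_force_max=bf,
        N_est=r.N,
        D_est=r.D,
        N_true=n_true,
        D_true=d_true,
        index_est=r.index_pct,
        grade_est=r.grade,
        true_index_planted=true_index,
        grade_true=assign_grade(true_index, cfg),
        valid=r.valid,
    )


@pytest.fixture(scope="session")
def benchmark_records() -> list[BenchRecord]:
    """Full pipeline runs over the default 20-fixture benchmark."""
    return [run_benchmark_fixture(seed) for seed in range(20)]


@pytest.fixture(scope="session")
def exactness_records():
    """(result, truth counts) for the disjoint-identical-nuclei fixtures."""
    out = []
    for seed in range(3):
        he, ds, ss, truth = generate_pair(exactness_spec(seed))
        r = run_same_field(he, ds)
        out.append((r, truth.truth_counts(truth.hotspot_window)))
    return out
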