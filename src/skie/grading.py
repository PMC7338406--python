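"""Ki-67 index computation, WHO 2017 grade assignment and the hot-spot
validity rule.

The Ki-67 index is the percentage of Ki-67-positive tumor nuclei (N) among
all tumor nuclei (D) within the assessed hot-spot. Grades follow the WHO 2017
cut-points for gastrointestinal neuroendocrine tumors: index < 3% is G1,
3-20% (boundaries inclusive) is G2, > 20% is G3. Grading always uses the
unrounded index; rounding is presentation-only, so a 2.96% index stays G1
even though it prints as 3.0%.

A hot-spot is valid for grading only if it contains at least
``min_tumor_cells`` (default 500) tumor nuclei, mirroring the clinical
requirement of counting 500-2000 tumor cells. The highest-ranked candidate
meeting the floor is graded; if none qualifies, the rank-1 candidate is
reported with ``valid = False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from .core import PipelineConfig, Window


@dataclass(frozen=True)
class KiIndexResult:
    N: int
    D: int
    index_pct: float
    grade: str
    window: Window
    valid: bool
    rank: int

    def __post_init__(self) -> None:
        if not (0 <= self.N <= self.D):
            raise ValueError(f"need 0 <= N <= D, got N={self.N}, D={self.D}")
        if not (0.0 <= self.index_pct <= 100.0):
            raise ValueError(f"index out of range: {self.index_pct}")


def compute_ki67_index(N: int, D: int) -> float:
    """Unrounded Ki-67 index 100*N/D in percent."""
    if D < 1:
        raise ValueError("D must be >= 1")
    if not (0 <= N <= D):
        raise ValueError(f"need 0 <= N <= D, got N={N}, D={D}")
    return 100.0 * N / D


def assign_grade(index_pct: float, config: PipelineConfig | None = None) -> str:
    """WHO grade from the (unrounded) index: < t_g1g2 is G1, up to and
    including t_g2g3 is G2, above is G3."""
    cfg = config or PipelineConfig()
    if not (0.0 <= index_pct <= 100.0):
        raise ValueError(f"index out of range: {index_pct}")
    if index_pct < cfg.t_g1g2:
        return "G1"
    if index_pct <= cfg.t_g2g3:
        return "G2"
    return "G3"


def make_result(N: int, D: int, window: Window, rank: int, config: PipelineConfig) -> KiIndexResult:
    """Assemble a per-candidate result; D = 0 yields a zero index, G1, invalid."""
    if D == 0:
        return KiIndexResult(N=0, D=0, index_pct=0.0, grade="G1", window=window, valid=False, rank=rank)
    idx = compute_ki67_index(N, D)
    return KiIndexResult(
        N=N,
        D=D,
        index_pct=idx,
        grade=assign_grade(idx, config),
        window=window,
        valid=D >= config.min_tumor_cells,
        rank=rank,
    )


def grade_hotspots(results: Sequence[KiIndexResult], config: PipelineConfig | None = None) -> KiIndexResult:
    """Pick the hot-spot to report: the highest-ranked candidate whose D meets
    the tumor-cell floor; otherwise the rank-1 candidate flagged invalid."""
    if not results:
        raise ValueError("no candidate results to grade")
    cfg = config or PipelineConfig()
    ranked = sorted(results, key=lambda r: r.rank)
    for res in ranked:
        if res.D >= cfg.min_tumor_cells:
            return res
    warnings.warn(
        f"no hot-spot window contains at least {cfg.min_tumor_cells} tumor cells; "
        "reporting the rank-1 candidate as invalid",
        stacklevel=2,
    )
    best = ranked[0]
    return KiIndexResult(
        N=best.N,
        D=best.D,
        index_pct=best.index_pct,
        grade=best.grade,
        window=best.window,
        valid=False,
        rank=best.rank,
    )
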