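"""Hot-spot detection: locate the 500 x 500 um fields with the highest
density of Ki-67-positive tumor nuclei.

A coarse 2D histogram of positive-nucleus centroids (bin side = window side)
localises high-density regions; candidate windows are then scored by the
exact centroid count inside each window, evaluated on a half-window-stride
grid so a true hot-spot straddling a histogram bin boundary is not split.
Up to ``n_candidates`` pairwise non-overlapping windows are selected greedily
by descending count, restricted to windows lying within the tumor region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PipelineConfig, RasterImage, Window
from .stain import BinaryMask, component_centroids


@dataclass(frozen=True)
class DensityMap:
    """Counts of positive-nucleus centroids per (window-sized) bin."""

    counts: np.ndarray  # (n_rows, n_cols) int
    bin_px: int  # bin side, in source-image pixels

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or np.any(c < 0):
            raise ValueError("density map must be a 2D array of non-negative counts")


@dataclass(frozen=True)
class HotSpotCandidate:
    window: Window
    score: int  # positive tumor nucleus centroids inside the window
    rank: int

    def __post_init__(self) -> None:
        if self.score < 0 or self.rank < 1:
            raise ValueError("invalid candidate")


def build_density_map(ki67_in_tumor_mask: BinaryMask, window_px: int, image_shape: tuple[int, int]) -> DensityMap:
    """Bin Ki-67-positive tumor nucleus centroids into a window-sized grid.

    Counts are conserved: the histogram total equals the number of centroids.
    """
    if window_px > min(image_shape):
        raise ValueError("window larger than image")
    cents = component_centroids(ki67_in_tumor_mask)
    n_rows = -(-image_shape[0] // window_px)
    n_cols = -(-image_shape[1] // window_px)
    counts = np.zeros((n_rows, n_cols), dtype=int)
    if len(cents):
        r = np.minimum((cents[:, 0] // window_px).astype(int), n_rows - 1)
        c = np.minimum((cents[:, 1] // window_px).astype(int), n_cols - 1)
        np.add.at(counts, (r, c), 1)
    return DensityMap(counts=counts, bin_px=window_px)


def _window_positions(image_shape: tuple[int, int], window_px: int, stride: int) -> list[tuple[int, int]]:
    """Row-major half-open window origins on a stride grid; the final
    row/column of positions is clamped so windows stay inside the image."""
    rows = list(range(0, image_shape[0] - window_px + 1, stride))
    cols = list(range(0, image_shape[1] - window_px + 1, stride))
    if rows and rows[-1] != image_shape[0] - window_px:
        rows.append(image_shape[0] - window_px)
    if cols and cols[-1] != image_shape[1] - window_px:
        cols.append(image_shape[1] - window_px)
    return [(r, c) for r in rows for c in cols]


def count_in_window(centroids: np.ndarray, window: Window) -> int:
    """Exact count of centroids whose (row, col) falls in the half-open window."""
    if len(centroids) == 0:
        return 0
    inside = (
        (centroids[:, 0] >= window.row0)
        & (centroids[:, 0] < window.row1)
        & (centroids[:, 1] >= window.col0)
        & (centroids[:, 1] < window.col1)
    )
    return int(inside.sum())


def _tumor_fraction(tumor_mask: BinaryMask, window: Window) -> float:
    s = tumor_mask.scale
    sub = tumor_mask.mask[window.row0 // s : -(-window.row1 // s), window.col0 // s : -(-window.col1 // s)]
    if sub.size == 0:
        return 0.0
    return float(sub.mean())


def _center_in_tumor(tumor_mask: BinaryMask, window: Window) -> bool:
    r, c = window.center
    s = tumor_mask.scale
    ri, ci = int(r / s), int(c / s)
    h, w = tumor_mask.mask.shape
    return 0 <= ri < h and 0 <= ci < w and bool(tumor_mask.mask[ri, ci])


def select_candidates(
    ki67_in_tumor_mask: BinaryMask,
    tumor_mask: BinaryMask,
    image_shape: tuple[int, int],
    window_px: int,
    config: PipelineConfig,
) -> list[HotSpotCandidate]:
    """Greedy selection of up to ``n_candidates`` non-overlapping hot-spot
    windows by descending exact positive-centroid count.

    A window is eligible if its center lies inside the tumor mask and at
    least ``tumor_window_fraction`` of its pixels are tumor-positive; windows
    with zero positives are never returned. Ties are broken by row-major
    window origin, making selection fully deterministic.
    """
    if not tumor_mask.mask.any():
        import warnings

        warnings.warn("no tumor pixels: no hot-spot candidates", stacklevel=2)
        return []
    stride = max(1, window_px // config.hotspot_stride_divisor)
    cents = component_centroids(ki67_in_tumor_mask)
    positions = _window_positions(image_shape, window_px, stride)
    scored: list[tuple[int, int, int]] = []
    for r, c in positions:
        w = Window(r, c, window_px, window_px)
        if not _center_in_tumor(tumor_mask, w):
            continue
        if _tumor_fraction(tumor_mask, w) < config.tumor_window_fraction:
            continue
        score = count_in_window(cents, w)
        if score > 0:
            scored.append((score, r, c))
    # descending score, then row-major origin for ties
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    selected: list[HotSpotCandidate] = []
    for score, r, c in scored:
        w = Window(r, c, window_px, window_px)
        if any(w.overlaps(s.window) for s in selected):
            continue
        selected.append(HotSpotCandidate(window=w, score=score, rank=len(selected) + 1))
        if len(selected) == config.n_candidates:
            break
    return selected


def brute_force_max_score(
    ki67_in_tumor_mask: BinaryMask,
    image_shape: tuple[int, int],
    window_px: int,
    stride: int,
) -> int:
    """Exhaustive maximum in-window centroid count over the stride grid
    (ignoring tumor-coverage eligibility); oracle for rank-1 scoring."""
    cents = component_centroids(ki67_in_tumor_mask)
    best = 0
    for r, c in _window_positions(image_shape, window_px, stride):
        best = max(best, count_in_window(cents, Window(r, c, window_px, window_px)))
    return best


def extract_fields(
    he_registered: RasterImage, ds: RasterImage, candidate: HotSpotCandidate
) -> tuple[RasterImage, RasterImage]:
    """Crop the candidate window from the registered H&E and the DS image.

    Both images live in the DS frame, so the crops are pixelwise co-located.
    """
    w = candidate.window
    assert w.contained_in(he_registered.shape) and w.contained_in(ds.shape), "window out of bounds"
    he_field = RasterImage(pixels=np.ascontiguousarray(w.crop(he_registered.pixels)), mpp=he_registered.mpp)
    ds_field = RasterImage(pixels=np.ascontiguousarray(w.crop(ds.pixels)), mpp=ds.mpp)
    return he_field, ds_field
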