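"""Tumor-nucleus segmentation and counting on the hot-spot fields.

Total tumor nuclei (the denominator D of the Ki-67 index) are measured on the
registered H&E field, where nuclear contrast is far better than under the
Permanent Red of the double stain. Pixels are clustered into k = 3 color
classes (white background, hematoxylin, eosin) by k-means; the hematoxylin
class inside the tumor region gives the nuclei mask.

Because nuclei clump, connected components cannot be counted directly.
Instead the count is estimated by an area ratio: the total nuclei-mask area
divided by the median area of "single" (non-clumped) components, where single
components are identified by an area threshold (default: at or below the 75th
percentile of component areas). The same area-ratio rule yields the positive
count N from the Ki-67 mask, degenerating to plain component counting when
positives are disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from sklearn.cluster import KMeans

from .core import PipelineConfig, RasterImage, Window
from .stain import BinaryMask

_MAX_KMEANS_FIT_PIXELS = 200_000


@dataclass(frozen=True)
class PixelClusterModel:
    """Fitted k-means pixel clustering with cluster-role assignment."""

    k: int
    centers: np.ndarray  # (k, 3) RGB
    roles: dict[str, int]  # background / hematoxylin / eosin -> cluster id


@dataclass(frozen=True)
class NucleusCountEstimate:
    total_area_px: int
    median_single_area_px: float
    estimated_count: int
    n_single_components: int


def _farthest_point_init(colors: np.ndarray, k: int) -> np.ndarray:
    """Deterministic seeding: greedily pick k mutually distant pixel colors,
    starting from the color farthest from the overall mean."""
    uniq = np.unique(colors, axis=0).astype(float)
    if len(uniq) < k:
        raise ValueError(f"field has only {len(uniq)} distinct colors; need >= {k}")
    mean = uniq.mean(axis=0)
    centers = [uniq[np.argmax(np.sum((uniq - mean) ** 2, axis=1))]]
    for _ in range(k - 1):
        d = np.min(
            np.stack([np.sum((uniq - c) ** 2, axis=1) for c in centers]), axis=0
        )
        centers.append(uniq[np.argmax(d)])
    return np.stack(centers)


def cluster_pixels(field: RasterImage, k: int = 3, seed: int = 0) -> tuple[np.ndarray, PixelClusterModel]:
    """Cluster field pixels into k color classes; returns (labels, model).

    Initialization is deterministic (farthest-point colors), and the fit runs
    on a regular pixel subsample for speed with prediction over all pixels,
    so repeated runs give identical labels. Roles: background = highest mean
    luminance cluster; hematoxylin = lowest mean (R - B); eosin = remaining.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    h, w = field.shape
    flat = field.pixels.reshape(-1, 3).astype(np.float32)
    if len(flat) < k:
        raise ValueError("field smaller than k pixels")
    step = max(1, len(flat) // _MAX_KMEANS_FIT_PIXELS)
    sample = flat[::step]
    init = _farthest_point_init(sample, k)
    km = KMeans(n_clusters=k, init=init, n_init=1, random_state=seed)
    km.fit(sample)
    labels = km.predict(flat).reshape(h, w)
    centers = km.cluster_centers_
    luminance = centers @ np.array([0.299, 0.587, 0.114])
    bg = int(np.argmax(luminance))
    r_minus_b = centers[:, 0] - centers[:, 2]
    order = np.argsort(r_minus_b)
    hema = int(order[0]) if int(order[0]) != bg else int(order[1])
    remaining = [i for i in range(k) if i not in (bg, hema)]
    eos = remaining[0] if remaining else hema
    model = PixelClusterModel(k=k, centers=centers, roles={"background": bg, "hematoxylin": hema, "eosin": eos})
    return labels, model


def nuclei_mask_from_clusters(
    labels: np.ndarray, model: PixelClusterModel, tumor_mask_field: np.ndarray, config: PipelineConfig
) -> BinaryMask:
    """Nuclei mask: hematoxylin-labelled pixels inside the tumor region,
    lightly opened and hole-filled. ``tumor_mask_field`` must already be at
    field resolution."""
    if labels.shape != tumor_mask_field.shape:
        raise ValueError("labels and tumor mask must share shape")
    raw = (labels == model.roles["hematoxylin"]) & tumor_mask_field.astype(bool)
    if config.nuclei_opening_radius > 0:
        raw = morphology.opening(raw, morphology.disk(config.nuclei_opening_radius))
    raw = ndimage.binary_fill_holes(raw)
    return BinaryMask(mask=raw, provenance="nuclei", scale=1)


def _component_areas(mask: np.ndarray, interior_only: bool = False) -> np.ndarray:
    """Areas of 8-connected components; with ``interior_only`` drop components
    touching the mask border (clipped nuclei, not representative singles)."""
    labels, n = measure.label(mask, return_num=True, connectivity=2)
    if n == 0:
        return np.zeros(0, dtype=int)
    areas = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    if interior_only:
        border = np.unique(
            np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
        )
        keep = np.setdiff1d(np.arange(1, n + 1), border[border > 0])
        areas = areas[keep - 1]
    return areas


def estimate_median_nucleus_area(mask: BinaryMask, config: PipelineConfig) -> NucleusCountEstimate:
    """Median area of single (non-clumped) nuclei, plus the resulting
    area-ratio count estimate for the whole mask.

    Components with area at or below the configured quantile of all component
    areas count as single nuclei; clumps (larger merged components) are
    excluded from the median but contribute to total area. Components clipped
    by the field border are excluded from the single-nucleus distribution
    (their area is not a nucleus area) but kept in the total.
    """
    areas = _component_areas(mask.mask)
    if len(areas) == 0:
        raise ValueError("empty mask: no nuclei detected")
    interior = _component_areas(mask.mask, interior_only=True)
    pool = interior if len(interior) else areas
    threshold = np.percentile(pool, config.single_nucleus_area_quantile)
    single = pool[pool <= threshold]
    if len(single) == 0:  # cannot happen with a percentile threshold, but be safe
        single = pool
    a_nuc = float(np.median(single))
    total = int(areas.sum())
    return NucleusCountEstimate(
        total_area_px=total,
        median_single_area_px=a_nuc,
        estimated_count=estimate_nucleus_count(total, a_nuc),
        n_single_components=len(single),
    )


def estimate_nucleus_count(total_area_px: float, a_nuc: float) -> int:
    """Area-ratio nucleus count: round(total area / median single-nucleus area)."""
    if a_nuc <= 0:
        raise ValueError("median nucleus area must be > 0")
    return int(round(total_area_px / a_nuc))


def count_total_nuclei(he_field: RasterImage, tumor_mask_field: np.ndarray, config: PipelineConfig) -> tuple[int, NucleusCountEstimate, BinaryMask]:
    """D for one hot-spot field: cluster pixels, build the nuclei mask, apply
    the area-ratio estimator. Returns (D, estimate, nuclei mask)."""
    labels, model = cluster_pixels(he_field, k=config.kmeans_k, seed=config.random_seed)
    mask = nuclei_mask_from_clusters(labels, model, tumor_mask_field, config)
    if not mask.mask.any():
        empty = NucleusCountEstimate(0, 0.0, 0, 0)
        return 0, empty, mask
    est = estimate_median_nucleus_area(mask, config)
    return est.estimated_count, est, mask


def count_positive_nuclei(
    ki67_in_tumor_mask: BinaryMask, window: Window, config: PipelineConfig
) -> int:
    """N for one hot-spot window from the Ki-67-positive tumor mask.

    The mask is cropped to the window (honouring the mask's scale). In
    ``area_ratio`` mode each component contributes max(1, round(area/A_pos))
    with A_pos the median single-positive area; in ``components`` mode each
    component counts once.
    """
    s = ki67_in_tumor_mask.scale
    sub = ki67_in_tumor_mask.mask[
        window.row0 // s : -(-window.row1 // s), window.col0 // s : -(-window.col1 // s)
    ]
    areas = _component_areas(sub)
    if len(areas) == 0:
        return 0
    if config.positive_count_mode == "components":
        return int(len(areas))
    interior = _component_areas(sub, interior_only=True)
    pool = interior if len(interior) else areas
    threshold = np.percentile(pool, config.single_nucleus_area_quantile)
    single = pool[pool <= threshold]
    a_pos = float(np.median(single if len(single) else pool))
    return int(sum(max(1, round(a / a_pos)) for a in areas))
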