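"""Optical-density color deconvolution and stain-mask extraction.

Light absorption by histology stains is multiplicative in transmitted
intensity and therefore additive in optical density (Beer-Lambert):

    OD_c = -log10((I_c + 1) / 255),  c in {R, G, B}

A pixel's OD vector is a non-negative combination of the unit OD vectors of
the stains present, so stacking those vectors as rows of a 3x3 matrix ``M``
gives ``OD = C @ M`` for per-stain concentrations ``C``; deconvolution is the
linear inversion ``C = OD @ M^-1``.

On the double-stained (DS) image the three stains are hematoxylin (blue
nuclear counterstain), DAB (brown, Ki-67-positive nuclei) and Permanent Red
(synaptophysin, tumor region). Segmentation of the DAB and Permanent-Red
channels into binary masks uses Otsu thresholding with an absolute OD floor,
followed by light morphological clean-up; both run on the DS image downscaled
by a factor of four, where stain boundaries remain clearly resolvable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology
from skimage.filters import threshold_otsu
from scipy import ndimage

from .core import PipelineConfig, RasterImage

OD_EPS = 1.0  # added to intensities so OD(0) is finite


@dataclass(frozen=True)
class StainMatrix:
    """Rows are unit-norm stain OD vectors in RGB order."""

    matrix: np.ndarray  # (3, 3)
    names: tuple[str, str, str]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("stain matrix must be 3x3")
        norms = np.linalg.norm(m, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero stain vector")
        object.__setattr__(self, "matrix", m / norms[:, None])
        if abs(np.linalg.det(self.matrix)) < 1e-8:
            raise ValueError("stain matrix is singular")

    @staticmethod
    def ds_default(config: PipelineConfig) -> "StainMatrix":
        return StainMatrix(
            matrix=np.array([config.od_hematoxylin, config.od_dab, config.od_permanent_red]),
            names=("hematoxylin", "dab", "permanent_red"),
        )

    @staticmethod
    def he_default(config: PipelineConfig) -> "StainMatrix":
        residual = np.cross(config.od_hematoxylin, config.od_eosin)
        return StainMatrix(
            matrix=np.array([config.od_hematoxylin, config.od_eosin, residual]),
            names=("hematoxylin", "eosin", "residual"),
        )

    def index_of(self, name: str) -> int:
        return self.names.index(name)


@dataclass(frozen=True)
class BinaryMask:
    """Boolean mask tied to its source image through an integer scale factor
    (mask pixel = ``scale`` x ``scale`` source pixels)."""

    mask: np.ndarray
    provenance: str  # synaptophysin | ki67 | ki67_in_tumor | nuclei
    scale: int = 1

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.dtype != bool:
            raise ValueError("mask must be boolean")
        if m.ndim != 2:
            raise ValueError("mask must be 2D")
        object.__setattr__(self, "mask", m)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def rgb_to_od(pixels: np.ndarray) -> np.ndarray:
    """Per-channel optical density of an 8-bit RGB array; white maps to ~0."""
    arr = np.asarray(pixels, dtype=np.float32)
    return -np.log10((arr + OD_EPS) / 255.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`, clipped into the 8-bit gamut."""
    intensity = 255.0 * np.power(10.0, -np.asarray(od, dtype=np.float64)) - OD_EPS
    return np.clip(np.rint(intensity), 0, 255).astype(np.uint8)


def color_deconvolve(image: RasterImage, M: StainMatrix, clip_negative: bool = True) -> np.ndarray:
    """Unmix an RGB image into per-stain concentrations (OD units).

    Returns an ``(H, W, 3)`` float array, channel order matching ``M.names``.
    Small negative concentrations (out-of-gamut colors) are clipped to zero
    unless ``clip_negative`` is False.
    """
    od = rgb_to_od(image.pixels)
    inv = np.linalg.inv(M.matrix)
    conc = od.reshape(-1, 3) @ inv
    conc = conc.reshape(od.shape)
    if clip_negative:
        conc = np.maximum(conc, 0.0)
    return conc


def reconstruct_od(concentrations: np.ndarray, M: StainMatrix) -> np.ndarray:
    """Forward model: OD = concentrations @ M (for round-trip checks)."""
    return np.asarray(concentrations) @ M.matrix


def downscale(image: RasterImage, factor: int) -> RasterImage:
    """Block-mean downscaling; mpp grows by the same factor.

    Ragged right/bottom edges are averaged over the partial block.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return image
    h, w = image.shape
    if factor > h or factor > w:
        raise ValueError("downscale factor exceeds image size")
    px = image.pixels.astype(np.float32)
    out_h, out_w = -(-h // factor), -(-w // factor)
    out = np.zeros((out_h, out_w, 3), dtype=np.float32)
    counts = np.zeros((out_h, out_w, 1), dtype=np.float32)
    # block accumulation that tolerates ragged edges
    for dr in range(factor):
        for dc in range(factor):
            sub = px[dr::factor, dc::factor]
            out[: sub.shape[0], : sub.shape[1]] += sub
            counts[: sub.shape[0], : sub.shape[1]] += 1
    out = np.clip(np.rint(out / counts), 0, 255).astype(np.uint8)
    return RasterImage(pixels=out, mpp=image.mpp * factor)


def _remove_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Drop connected components with fewer than ``min_area`` pixels."""
    labels, n = measure.label(mask, return_num=True, connectivity=2)
    if n == 0:
        return mask
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    keep = areas >= min_area
    keep[0] = False
    return keep[labels]


def _threshold_channel(channel: np.ndarray, od_floor: float) -> np.ndarray:
    """Otsu threshold with an absolute OD floor against near-empty channels."""
    finite = channel[np.isfinite(channel)]
    if finite.size == 0 or float(finite.max()) <= od_floor:
        return np.zeros_like(channel, dtype=bool)
    try:
        t = threshold_otsu(channel)
    except ValueError:  # constant channel
        return np.zeros_like(channel, dtype=bool)
    return channel > max(t, od_floor)


def segment_ki67(
    channels: np.ndarray, M: StainMatrix, config: PipelineConfig, scale: int | None = None
) -> BinaryMask:
    """Binary mask of DAB-positive (Ki-67-positive) nuclei.

    Threshold on the DAB concentration channel, then an opening to detach
    touching debris and removal of components below the minimum area.
    """
    if channels.size == 0:
        raise ValueError("empty image")
    dab = channels[..., M.index_of("dab")]
    raw = _threshold_channel(dab, config.od_floor)
    if config.ki67_opening_radius > 0:
        raw = morphology.opening(raw, morphology.disk(config.ki67_opening_radius))
    raw = _remove_small(raw, config.min_object_area_px)
    return BinaryMask(mask=raw, provenance="ki67", scale=scale or config.deconv_downscale)


def segment_synaptophysin(
    channels: np.ndarray, M: StainMatrix, config: PipelineConfig, scale: int | None = None
) -> BinaryMask:
    """Binary mask of the synaptophysin-positive (Permanent Red) tumor region.

    Threshold on the Permanent-Red channel, closing to bridge stain texture,
    hole filling (nuclei punch holes in the red region), and small-object
    removal. The minimum object area for the region mask is much larger than
    for nuclei: isolated specks of red are not tumor.
    """
    if channels.size == 0:
        raise ValueError("empty image")
    red = channels[..., M.index_of("permanent_red")]
    raw = _threshold_channel(red, config.od_floor)
    if config.synapto_closing_radius > 0:
        raw = morphology.closing(raw, morphology.disk(config.synapto_closing_radius))
    raw = ndimage.binary_fill_holes(raw)
    raw = _remove_small(raw, max(config.min_object_area_px, 64))
    return BinaryMask(mask=raw, provenance="synaptophysin", scale=scale or config.deconv_downscale)


def segment_ki67_field(ds_field: RasterImage, tumor_field: np.ndarray, config: PipelineConfig) -> BinaryMask:
    """Full-resolution Ki-67-positive-in-tumor mask for one hot-spot field.

    Whole-slide masks are computed at 1/4 scale, which is ample for tumor
    localisation and hot-spot detection, but too coarse for stable
    single-nucleus areas; counting inside the selected window therefore
    re-runs deconvolution and thresholding on the full-resolution DS crop,
    with morphology radii and the minimum area scaled accordingly.
    """
    f = config.deconv_downscale
    M = StainMatrix.ds_default(config)
    channels = color_deconvolve(ds_field, M)
    dab = channels[..., M.index_of("dab")]
    raw = _threshold_channel(dab, config.od_floor)
    radius = config.ki67_opening_radius * f
    if radius > 0:
        raw = morphology.opening(raw, morphology.disk(radius))
    raw = _remove_small(raw, config.min_object_area_px * f * f)
    raw &= tumor_field.astype(bool)
    return BinaryMask(mask=raw, provenance="ki67_in_tumor", scale=1)


def ki67_in_tumor(ki67: BinaryMask, synapto: BinaryMask) -> BinaryMask:
    """Ki-67-positive tumor nuclei = pixelwise AND of the two masks."""
    if ki67.mask.shape != synapto.mask.shape or ki67.scale != synapto.scale:
        raise ValueError("masks must share shape and scale")
    return BinaryMask(mask=ki67.mask & synapto.mask, provenance="ki67_in_tumor", scale=ki67.scale)


def mask_components(mask: BinaryMask) -> tuple[np.ndarray, int]:
    """8-connected component labels of a mask and their count."""
    labels, n = measure.label(mask.mask, return_num=True, connectivity=2)
    return labels, n


def component_centroids(mask: BinaryMask) -> np.ndarray:
    """(n, 2) array of component centroids in *source-image* (row, col)
    pixel coordinates (mask coordinates scaled up by ``mask.scale``)."""
    labels, n = mask_components(mask)
    if n == 0:
        return np.zeros((0, 2), dtype=float)
    cents = np.asarray(ndimage.center_of_mass(mask.mask, labels, range(1, n + 1)), dtype=float)
    return cents * mask.scale
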