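"""Landmark-based similarity registration of the H&E section onto the
double-stained (DS) section.

Adjacent tissue sections are related, to good approximation, by a similarity
transform (uniform scale, rotation, translation); the user supplies paired
landmarks and the transform is estimated in closed form by least squares
(Umeyama/Procrustes with scale). Reflections are rejected: adjacent sections
are never mirrored. The H&E image is always warped into the DS frame, which
is the reference frame for hot-spot detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import transform as sktransform

from .core import RasterImage


@dataclass(frozen=True)
class SimilarityTransform:
    """Maps H&E-frame (x, y) points to DS-frame points:
    ``p' = s * R(theta) @ p + t``."""

    scale: float
    rotation: float
    tx: float
    ty: float

    def __post_init__(self) -> None:
        if not (self.scale > 0):
            raise ValueError(f"scale must be > 0, got {self.scale}")

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        m = np.array(
            [
                [self.scale * c, -self.scale * s, self.tx],
                [self.scale * s, self.scale * c, self.ty],
                [0.0, 0.0, 1.0],
            ]
        )
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 2) array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        h = np.column_stack([pts, np.ones(len(pts))])
        out = (self.matrix @ h.T).T
        return out[:, :2]

    def inverse(self) -> "SimilarityTransform":
        c, s = np.cos(-self.rotation), np.sin(-self.rotation)
        inv_scale = 1.0 / self.scale
        tx = -inv_scale * (c * self.tx - s * self.ty)
        ty = -inv_scale * (s * self.tx + c * self.ty)
        return SimilarityTransform(scale=inv_scale, rotation=-self.rotation, tx=tx, ty=ty)

    @staticmethod
    def identity() -> "SimilarityTransform":
        return SimilarityTransform(scale=1.0, rotation=0.0, tx=0.0, ty=0.0)

    @staticmethod
    def from_matrix(m: np.ndarray) -> "SimilarityTransform":
        a, b = m[0, 0], m[1, 0]
        scale = float(np.hypot(a, b))
        return SimilarityTransform(
            scale=scale, rotation=float(np.arctan2(b, a)), tx=float(m[0, 2]), ty=float(m[1, 2])
        )


class LandmarkError(ValueError):
    pass


def load_landmarks(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read landmark pairs from CSV rows ``x_he, y_he, x_ds, y_ds`` (0-based
    pixel units). A single header line is tolerated."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            try:
                rows.append([float(p) for p in parts[:4]])
            except ValueError:
                continue  # header
    if not rows:
        raise LandmarkError(f"no landmark rows found in {path}")
    arr = np.asarray(rows, dtype=float)
    return arr[:, 0:2], arr[:, 2:4]


def save_landmarks(src: np.ndarray, dst: np.ndarray, path: str | Path) -> None:
    arr = np.column_stack([src, dst])
    header = "x_he,y_he,x_ds,y_ds"
    np.savetxt(path, arr, delimiter=",", header=header, comments="", fmt="%.6f")


def estimate_similarity(src: np.ndarray, dst: np.ndarray) -> SimilarityTransform:
    """Least-squares similarity transform taking ``src`` (H&E) landmarks onto
    ``dst`` (DS) landmarks.

    Uses the closed-form Umeyama solution, which minimises the summed squared
    residuals over all pairs; it is exact for noiseless correspondences.

    Raises
    ------
    LandmarkError
        For fewer than 2 pairs, duplicated source points, or a degenerate
        configuration where scale/rotation is unidentifiable.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise LandmarkError("landmarks must be two equal-length (n, 2) arrays")
    if len(src) < 2:
        raise LandmarkError("at least 2 landmark pairs are required")
    # duplicate source points carry no new constraint and break identifiability at n=2
    if len(np.unique(src, axis=0)) < len(src):
        raise LandmarkError("duplicate source landmarks")
    tf = sktransform.SimilarityTransform.from_estimate(src, dst)
    if not tf or not np.all(np.isfinite(tf.params)):
        raise LandmarkError("degenerate landmark configuration")
    result = SimilarityTransform.from_matrix(tf.params)
    if np.linalg.det(result.matrix[:2, :2]) <= 0:
        raise LandmarkError("estimated transform is a reflection; landmarks are inconsistent")
    return result


def registration_residual(T: SimilarityTransform, src: np.ndarray, dst: np.ndarray, mpp: float = 1.0) -> float:
    """RMS Euclidean residual of the fitted transform over the landmark pairs,
    in microns (``mpp`` converts pixels to microns)."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    res = T.apply(src) - dst
    rms_px = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    return rms_px * mpp


def apply_transform(
    image: RasterImage,
    T: SimilarityTransform,
    out_shape: tuple[int, int],
    fill: int = 255,
) -> RasterImage:
    """Resample the H&E image into the DS frame.

    ``T`` maps H&E coordinates to DS coordinates; warping uses the inverse map
    with bilinear interpolation. Pixels with no H&E support are filled white,
    matching histology background.
    """
    # skimage's inverse_map takes output (DS) coords to input (H&E) coords
    inv = sktransform.SimilarityTransform(matrix=T.inverse().matrix)
    warped = sktransform.warp(
        image.pixels,
        inverse_map=inv,
        output_shape=(out_shape[0], out_shape[1], 3),
        order=1,
        cval=fill / 255.0,
        preserve_range=False,
    )
    out = np.clip(np.rint(warped * 255.0), 0, 255).astype(np.uint8)
    return RasterImage(pixels=out, mpp=image.mpp)
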