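"""Shared image and geometry primitives, pipeline configuration and report I/O.

Conventions used throughout the package:

* pixel coordinates are 0-based, row-major ``(row, col)``;
* windows are half-open intervals ``[row0, row0 + height_px)``;
* the physical position of pixel ``(r, c)`` is ``(r * mpp, c * mpp)`` microns,
  measured at the pixel's top-left corner;
* every image carries a single isotropic microns-per-pixel (mpp) value.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
from PIL import Image
import tifffile


@dataclass(frozen=True)
class RasterImage:
    """An 8-bit RGB raster with an isotropic physical pixel size.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8 array.
    mpp
        Microns per pixel, strictly positive and identical in both axes.
    """

    pixels: np.ndarray
    mpp: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected an (H, W, 3) RGB array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must contain at least one pixel")
        if px.dtype != np.uint8:
            raise ValueError(f"expected uint8 pixels, got {px.dtype}")
        if not (self.mpp > 0):
            raise ValueError(f"mpp must be > 0, got {self.mpp}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) in pixels."""
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass(frozen=True)
class Window:
    """A half-open axis-aligned pixel window ``[row0, row0+h) x [col0, col0+w)``."""

    row0: int
    col0: int
    height_px: int
    width_px: int

    def __post_init__(self) -> None:
        if self.height_px < 1 or self.width_px < 1:
            raise ValueError("window extent must be >= 1 px")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("window origin must be non-negative")

    @property
    def row1(self) -> int:
        return self.row0 + self.height_px

    @property
    def col1(self) -> int:
        return self.col0 + self.width_px

    @property
    def center(self) -> tuple[float, float]:
        return self.row0 + self.height_px / 2.0, self.col0 + self.width_px / 2.0

    def contained_in(self, shape: tuple[int, int]) -> bool:
        return self.row1 <= shape[0] and self.col1 <= shape[1]

    def overlaps(self, other: "Window") -> bool:
        return not (
            self.row1 <= other.row0
            or other.row1 <= self.row0
            or self.col1 <= other.col0
            or other.col1 <= self.col0
        )

    def crop(self, pixels: np.ndarray) -> np.ndarray:
        return pixels[self.row0 : self.row1, self.col0 : self.col1]

    def to_um(self, mpp: float) -> tuple[float, float, float, float]:
        """(row0_um, col0_um, height_um, width_um) of the window."""
        return (self.row0 * mpp, self.col0 * mpp, self.height_px * mpp, self.width_px * mpp)

    @staticmethod
    def from_um(row0_um: float, col0_um: float, height_um: float, width_um: float, mpp: float) -> "Window":
        return Window(
            row0=int(round(row0_um / mpp)),
            col0=int(round(col0_um / mpp)),
            height_px=max(1, int(round(height_um / mpp))),
            width_px=max(1, int(round(width_um / mpp))),
        )


def um_to_px(length_um: float, mpp: float) -> int:
    """Convert a physical length in microns to a pixel count.

    Positive lengths never collapse to zero pixels, so a physically specified
    window always has at least one-pixel extent.
    """
    if length_um < 0:
        raise ValueError(f"length must be >= 0, got {length_um}")
    if not (mpp > 0):
        raise ValueError(f"mpp must be > 0, got {mpp}")
    if length_um == 0:
        return 0
    return max(1, int(round(length_um / mpp)))


# Published Ruifrok-Johnston optical-density vectors for hematoxylin and DAB;
# the Permanent Red vector is the one used by the synthetic palette (strong
# green absorption, moderate blue), estimated once and fixed in config.
DEFAULT_HEMATOXYLIN_OD = (0.650, 0.704, 0.286)
DEFAULT_DAB_OD = (0.268, 0.570, 0.776)
DEFAULT_PERMANENT_RED_OD = (0.214, 0.851, 0.478)
DEFAULT_EOSIN_OD = (0.072, 0.990, 0.105)


@dataclass
class PipelineConfig:
    """Flat configuration for every pipeline stage.

    Defaults are the pipeline's operating constants: 500 x 500 um^2 hot-spot
    fields, five candidates, a 500-tumor-cell validity floor, stain separation
    at 1/4 scale, k = 3 pixel clusters on the H&E field, WHO grade cut-points
    at 3% and 20%, and tile rules at 70% background / 20% synaptophysin.
    """

    hotspot_side_um: float = 500.0
    n_candidates: int = 5
    min_tumor_cells: int = 500
    deconv_downscale: int = 4
    kmeans_k: int = 3
    t_g1g2: float = 3.0
    t_g2g3: float = 20.0
    tile_background_threshold: float = 70.0
    tile_synaptophysin_threshold: float = 20.0

    # stain optical-density unit vectors (RGB order)
    od_hematoxylin: tuple[float, float, float] = DEFAULT_HEMATOXYLIN_OD
    od_dab: tuple[float, float, float] = DEFAULT_DAB_OD
    od_permanent_red: tuple[float, float, float] = DEFAULT_PERMANENT_RED_OD
    od_eosin: tuple[float, float, float] = DEFAULT_EOSIN_OD

    # thresholding / morphology (applied at the deconvolution scale)
    od_floor: float = 0.15
    ki67_opening_radius: int = 1
    synapto_closing_radius: int = 2
    min_object_area_px: int = 4

    # hot-spot selection
    hotspot_stride_divisor: int = 2
    tumor_window_fraction: float = 0.5

    # nuclei quantification
    nuclei_opening_radius: int = 1
    single_nucleus_area_quantile: float = 75.0
    positive_count_mode: str = "area_ratio"  # or "components"

    # tile labelling: background pixel = low saturation AND high value (HSV)
    background_saturation_max: float = 0.05
    background_value_min: float = 0.85

    random_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.t_g1g2 < self.t_g2g3 <= 100):
            raise ValueError("grade thresholds must satisfy 0 < t_g1g2 < t_g2g3 <= 100")
        for name in ("n_candidates", "min_tumor_cells", "deconv_downscale", "kmeans_k"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.hotspot_side_um <= 0:
            raise ValueError("hotspot_side_um must be > 0")
        if self.positive_count_mode not in ("area_ratio", "components"):
            raise ValueError("positive_count_mode must be 'area_ratio' or 'components'")

    def hotspot_side_px(self, mpp: float) -> int:
        return um_to_px(self.hotspot_side_um, mpp)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        kwargs: dict[str, Any] = {}
        fields = {f.name for f in dataclasses.fields(cls)}
        for k, v in d.items():
            if k not in fields:
                raise KeyError(f"unknown config key: {k}")
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))


def load_image(path: str | Path, mpp: float) -> RasterImage:
    """Load an 8-bit RGB TIFF or PNG as a :class:`RasterImage`.

    Grayscale and paletted inputs are rejected; an alpha channel is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not (mpp > 0):
        raise ValueError(f"mpp must be > 0, got {mpp}")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        with Image.open(path) as im:
            if im.mode not in ("RGB", "RGBA"):
                raise ValueError(f"expected an RGB image, got mode {im.mode!r}")
            arr = np.asarray(im.convert("RGB"))
    arr = np.asarray(arr)
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise ValueError(f"expected an RGB image, got array shape {arr.shape}")
    arr = arr[..., :3]
    if arr.dtype != np.uint8:
        raise ValueError(f"expected 8-bit pixels, got {arr.dtype}")
    return RasterImage(pixels=arr, mpp=mpp)


def save_image(image: RasterImage, path: str | Path) -> None:
    """Write the RGB pixels losslessly as PNG or (uncompressed) TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels)
    else:
        Image.fromarray(image.pixels, mode="RGB").save(path)


_REPORT_FIELDS = [
    "rank",
    "row0_px",
    "col0_px",
    "height_px",
    "width_px",
    "row0_um",
    "col0_um",
    "side_um",
    "N",
    "D",
    "index_pct",
    "index_pct_rounded",
    "grade",
    "valid",
]


def _result_row(res: Any, mpp: float) -> dict[str, Any]:
    w: Window = res.window
    return {
        "rank": res.rank,
        "row0_px": w.row0,
        "col0_px": w.col0,
        "height_px": w.height_px,
        "width_px": w.width_px,
        "row0_um": w.row0 * mpp,
        "col0_um": w.col0 * mpp,
        "side_um": w.height_px * mpp,
        "N": res.N,
        "D": res.D,
        "index_pct": res.index_pct,
        "index_pct_rounded": round(res.index_pct, 1),
        "grade": res.grade,
        "valid": res.valid,
    }


def write_report(results: Sequence[Any], path: str | Path, format: str = "csv", mpp: float = 1.0) -> None:
    """Write per-hot-spot results (window, N, D, index raw + rounded, grade,
    validity) as CSV or JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [_result_row(r, mpp) for r in results]
    if format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_REPORT_FIELDS)
            writer.writeheader()
            writer.writerows(rows)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump({"results": rows}, fh, indent=2)
    else:
        raise ValueError(f"unknown report format: {format!r}")


def read_report(path: str | Path) -> list[dict[str, Any]]:
    """Read back a report written by :func:`write_report`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            return json.load(fh)["results"]
    with open(path, newline="") as fh:
        out = []
        for row in csv.DictReader(fh):
            for k in ("rank", "row0_px", "col0_px", "height_px", "width_px", "N", "D"):
                row[k] = int(row[k])
            for k in ("row0_um", "col0_um", "side_um", "index_pct", "index_pct_rounded"):
                row[k] = float(row[k])
            row["valid"] = row["valid"] in ("True", "true", "1")
            out.append(row)
        return out
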