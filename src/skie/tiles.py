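"""Rule-based tile labelling and whole-slide tumor-grade heatmaps.

The registered pair is cut into hot-spot-sized tiles and each tile receives
one of four classes by a strict precedence:

* class 0 (background) — more than 70% background pixels (low-saturation,
  high-value in HSV);
* class 1 (non-tumor) — less than 20% synaptophysin-stained pixels;
* class 2 (G1 tumor) — eligible tile with a tile-local Ki-67 index < 3%;
* class 3 (G2 tumor) — eligible tile with index >= 3% (an index above 20%
  is flagged rather than given a class of its own).

These labels form the ground truth a downstream tile classifier can train
on; the labelled tiles are exported in a ``class_<k>/`` directory layout
with a manifest, and the label grid renders as a 4-color heatmap.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.color import rgb2hsv

from .core import PipelineConfig, RasterImage, Window, save_image
from .grading import compute_ki67_index
from .nuclei import count_positive_nuclei, count_total_nuclei
from .stain import BinaryMask

# class id -> display color (RGB); 0 background, 1 non-tumor, 2 G1, 3 G2
HEATMAP_COLORS: dict[int, tuple[int, int, int]] = {
    0: (245, 245, 245),
    1: (70, 115, 190),
    2: (90, 180, 90),
    3: (230, 150, 40),
}


@dataclass(frozen=True)
class TileLabel:
    window: Window
    class_id: int
    background_fraction: float
    synaptophysin_fraction: float
    tile_ki67_index: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.class_id not in (0, 1, 2, 3):
            raise ValueError(f"invalid class id {self.class_id}")


def tile_grid(image_shape: tuple[int, int], tile_px: int) -> list[Window]:
    """Row-major non-overlapping tile windows; ragged remainders dropped."""
    if tile_px > min(image_shape):
        raise ValueError("tile larger than image")
    return [
        Window(r, c, tile_px, tile_px)
        for r in range(0, image_shape[0] - tile_px + 1, tile_px)
        for c in range(0, image_shape[1] - tile_px + 1, tile_px)
    ]


def background_fraction(tile_rgb: np.ndarray, config: PipelineConfig | None = None) -> float:
    """Fraction of background pixels: low saturation AND high value in HSV."""
    cfg = config or PipelineConfig()
    hsv = rgb2hsv(tile_rgb)
    bg = (hsv[..., 1] < cfg.background_saturation_max) & (hsv[..., 2] > cfg.background_value_min)
    return float(bg.mean())


def _mask_fraction(mask: BinaryMask, window: Window) -> float:
    s = mask.scale
    sub = mask.mask[window.row0 // s : -(-window.row1 // s), window.col0 // s : -(-window.col1 // s)]
    return float(sub.mean()) if sub.size else 0.0


def _tumor_mask_at_field(tumor_mask: BinaryMask, window: Window) -> np.ndarray:
    """Nearest-neighbour upscale of the tumor mask crop to window resolution."""
    s = tumor_mask.scale
    sub = tumor_mask.mask[window.row0 // s : -(-window.row1 // s), window.col0 // s : -(-window.col1 // s)]
    up = np.repeat(np.repeat(sub, s, axis=0), s, axis=1)
    return up[: window.height_px, : window.width_px]


def label_tile(
    window: Window,
    he_registered: RasterImage,
    ds: RasterImage,
    tumor_mask: BinaryMask,
    ki67_in_tumor_mask: BinaryMask,
    config: PipelineConfig,
) -> TileLabel:
    """Apply the class-precedence rules to one tile of the registered pair."""
    ds_tile = window.crop(ds.pixels)
    bg_frac = background_fraction(ds_tile, config)
    if bg_frac * 100.0 > config.tile_background_threshold:
        return TileLabel(window, 0, bg_frac, _mask_fraction(tumor_mask, window))
    syn_frac = _mask_fraction(tumor_mask, window)
    if syn_frac * 100.0 < config.tile_synaptophysin_threshold:
        return TileLabel(window, 1, bg_frac, syn_frac)
    he_tile = RasterImage(pixels=np.ascontiguousarray(window.crop(he_registered.pixels)), mpp=he_registered.mpp)
    tumor_field = _tumor_mask_at_field(tumor_mask, window)
    d, _, _ = count_total_nuclei(he_tile, tumor_field, config)
    if d == 0:
        return TileLabel(window, 1, bg_frac, syn_frac, flags=("no_nuclei",))
    from .stain import segment_ki67_field

    ds_tile = RasterImage(pixels=np.ascontiguousarray(ds_tile), mpp=ds.mpp)
    pos_field = segment_ki67_field(ds_tile, tumor_field, config)
    tile_window = Window(0, 0, window.height_px, window.width_px)
    n = min(count_positive_nuclei(pos_field, tile_window, config), d)
    idx = compute_ki67_index(n, d)
    flags = ("index_gt_20",) if idx > config.t_g2g3 else ()
    class_id = 2 if idx < config.t_g1g2 else 3
    return TileLabel(window, class_id, bg_frac, syn_frac, tile_ki67_index=idx, flags=flags)


def label_tiles(
    he_registered: RasterImage,
    ds: RasterImage,
    tumor_mask: BinaryMask,
    ki67_in_tumor_mask: BinaryMask,
    config: PipelineConfig,
    tile_px: int | None = None,
) -> tuple[list[TileLabel], tuple[int, int]]:
    """Label every tile of the grid; returns (labels, grid shape)."""
    tile_px = tile_px or config.hotspot_side_px(ds.mpp)
    windows = tile_grid(ds.shape, tile_px)
    labels = [
        label_tile(w, he_registered, ds, tumor_mask, ki67_in_tumor_mask, config) for w in windows
    ]
    grid = (ds.shape[0] // tile_px, ds.shape[1] // tile_px)
    return labels, grid


def render_heatmap(labels: list[TileLabel], grid_shape: tuple[int, int], cell_px: int = 16) -> RasterImage:
    """Render the label grid as an RGB heatmap, one colored cell per tile."""
    n_r, n_c = grid_shape
    if len(labels) != n_r * n_c:
        raise ValueError(f"expected {n_r * n_c} labels for grid {grid_shape}, got {len(labels)}")
    img = np.zeros((n_r, n_c, 3), dtype=np.uint8)
    for i, lab in enumerate(labels):
        img[i // n_c, i % n_c] = HEATMAP_COLORS[lab.class_id]
    img = np.repeat(np.repeat(img, cell_px, axis=0), cell_px, axis=1)
    return RasterImage(pixels=img, mpp=1.0)


def export_labeled_tiles(
    ds: RasterImage, labels: list[TileLabel], out_dir: str | Path, he_registered: RasterImage | None = None
) -> Path:
    """Write each DS tile (and optionally its H&E counterpart) as PNG under
    ``out_dir/class_<k>/`` with a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    rows = []
    for i, lab in enumerate(labels):
        cls_dir = out_dir / f"class_{lab.class_id}"
        cls_dir.mkdir(exist_ok=True)
        name = f"tile_{i:05d}.png"
        tile = RasterImage(pixels=np.ascontiguousarray(lab.window.crop(ds.pixels)), mpp=ds.mpp)
        save_image(tile, cls_dir / name)
        if he_registered is not None:
            he_tile = RasterImage(
                pixels=np.ascontiguousarray(lab.window.crop(he_registered.pixels)), mpp=he_registered.mpp
            )
            save_image(he_tile, cls_dir / f"tile_{i:05d}_he.png")
        rows.append(
            {
                "path": f"class_{lab.class_id}/{name}",
                "row0": lab.window.row0,
                "col0": lab.window.col0,
                "tile_px": lab.window.height_px,
                "class": lab.class_id,
                "background_fraction": f"{lab.background_fraction:.6f}",
                "synaptophysin_fraction": f"{lab.synaptophysin_fraction:.6f}",
                "ki67_index": "" if lab.tile_ki67_index is None else f"{lab.tile_ki67_index:.6f}",
                "flags": ";".join(lab.flags),
            }
        )
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()) if rows else ["path"])
        writer.writeheader()
        writer.writerows(rows)
    return manifest
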