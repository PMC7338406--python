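"""End-to-end orchestration: registration -> stain separation -> hot-spot
detection -> nuclei counting -> grading, plus the tile-heatmap run.

Each stage is a pure function of (inputs, config); the orchestrator only
composes them and records a run manifest (inputs, config snapshot, seed,
timings, warnings) so every report is reproducible from its manifest.
"""

from __future__ import annotations

import json
import logging
import time
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .core import PipelineConfig, RasterImage, Window, load_image, save_image, write_report
from .grading import KiIndexResult, grade_hotspots, make_result
from .hotspot import HotSpotCandidate, build_density_map, extract_fields, select_candidates
from .nuclei import count_positive_nuclei, count_total_nuclei
from .registration import (
    SimilarityTransform,
    apply_transform,
    estimate_similarity,
    load_landmarks,
    registration_residual,
)
from .stain import (
    BinaryMask,
    StainMatrix,
    color_deconvolve,
    downscale,
    ki67_in_tumor,
    segment_ki67,
    segment_ki67_field,
    segment_synaptophysin,
)
from .tiles import export_labeled_tiles, label_tiles, render_heatmap

log = logging.getLogger("skie")


@dataclass
class RunManifest:
    inputs: dict
    config: dict
    version: str = __version__
    seed: int = 0
    timings_s: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


@dataclass
class SkieRun:
    """Everything a SKIE analysis produced."""

    result: KiIndexResult | None
    candidates: list[HotSpotCandidate]
    candidate_results: list[KiIndexResult]
    transform: SimilarityTransform
    residual_um: float
    tumor_mask: BinaryMask
    ki67_mask: BinaryMask
    ki67_in_tumor_mask: BinaryMask
    manifest: RunManifest


def _separate_stains(ds: RasterImage, config: PipelineConfig):
    """Downscale the DS image and produce the tumor / Ki-67 / intersection masks."""
    small = downscale(ds, config.deconv_downscale)
    M = StainMatrix.ds_default(config)
    channels = color_deconvolve(small, M)
    tumor = segment_synaptophysin(channels, M, config)
    ki67 = segment_ki67(channels, M, config)
    both = ki67_in_tumor(ki67, tumor)
    return tumor, ki67, both


def _count_candidate(
    he_reg: RasterImage,
    ds: RasterImage,
    tumor_mask: BinaryMask,
    both_mask: BinaryMask,
    cand: HotSpotCandidate,
    config: PipelineConfig,
) -> KiIndexResult:
    from .tiles import _tumor_mask_at_field  # shared nearest-neighbour upscale

    he_field, ds_field = extract_fields(he_reg, ds, cand)
    tumor_field = _tumor_mask_at_field(tumor_mask, cand.window)
    d, _, _ = count_total_nuclei(he_field, tumor_field, config)
    # positives are counted on a full-resolution mask of the field: the
    # 1/4-scale WSI mask localises hot-spots but quantises nucleus areas
    pos_field = segment_ki67_field(ds_field, tumor_field, config)
    field_window = Window(0, 0, cand.window.height_px, cand.window.width_px)
    n = min(count_positive_nuclei(pos_field, field_window, config), d)
    return make_result(N=n, D=d, window=cand.window, rank=cand.rank, config=config)


def analyze_pair(
    he: RasterImage,
    ds: RasterImage,
    landmarks_src: np.ndarray,
    landmarks_dst: np.ndarray,
    config: PipelineConfig | None = None,
) -> SkieRun:
    """Run the full SKIE analysis on in-memory images.

    ``landmarks_src`` are H&E-frame (x, y) points, ``landmarks_dst`` their DS
    counterparts.
    """
    cfg = config or PipelineConfig()
    manifest = RunManifest(inputs={"mode": "in-memory"}, config=cfg.to_dict(), seed=cfg.random_seed)
    timings = manifest.timings_s

    t0 = time.perf_counter()
    T = estimate_similarity(landmarks_src, landmarks_dst)
    residual = registration_residual(T, landmarks_src, landmarks_dst, mpp=ds.mpp)
    he_reg = apply_transform(he, T, out_shape=ds.shape)
    timings["registration"] = round(time.perf_counter() - t0, 3)
    log.info("registration: s=%.4f theta=%.4f t=(%.1f, %.1f) rms=%.2f um", T.scale, T.rotation, T.tx, T.ty, residual)

    t0 = time.perf_counter()
    tumor, ki67, both = _separate_stains(ds, cfg)
    timings["stain_separation"] = round(time.perf_counter() - t0, 3)
    log.info("masks: tumor area %d px, ki67 area %d px (1/%d scale)", tumor.area, ki67.area, tumor.scale)

    if not tumor.mask.any():
        manifest.warnings.append("no tumor detected: synaptophysin mask is empty")
        log.warning("no tumor detected")
        return SkieRun(None, [], [], T, residual, tumor, ki67, both, manifest)

    t0 = time.perf_counter()
    window_px = cfg.hotspot_side_px(ds.mpp)
    density = build_density_map(both, window_px, ds.shape)
    candidates = select_candidates(both, tumor, ds.shape, window_px, cfg)
    timings["hotspot_detection"] = round(time.perf_counter() - t0, 3)
    log.info("hot-spots: %d candidates, best score %s", len(candidates), candidates[0].score if candidates else "-")

    if not candidates:
        manifest.warnings.append("no candidate hot-spot windows found")
        return SkieRun(None, [], [], T, residual, tumor, ki67, both, manifest)

    t0 = time.perf_counter()
    cand_results = [_count_candidate(he_reg, ds, tumor, both, c, cfg) for c in candidates]
    timings["nuclei_quantification"] = round(time.perf_counter() - t0, 3)

    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        final = grade_hotspots(cand_results, cfg)
    for w in caught:  # record in the manifest, then re-emit for the caller
        manifest.warnings.append(str(w.message))
        _warnings.warn(w.message, stacklevel=2)
    log.info("result: N=%d D=%d index=%.2f%% grade=%s valid=%s", final.N, final.D, final.index_pct, final.grade, final.valid)
    return SkieRun(final, candidates, cand_results, T, residual, tumor, ki67, both, manifest)


def run_skie(
    he_path: str | Path,
    ds_path: str | Path,
    landmarks_path: str | Path,
    config: PipelineConfig | None = None,
    mpp: float = 0.5,
    out_dir: str | Path | None = None,
) -> SkieRun:
    """Path-based entry point: load images and landmarks, analyze, and (if
    ``out_dir`` is given) write report CSV/JSON and the run manifest."""
    cfg = config or PipelineConfig()
    he = load_image(he_path, mpp)
    ds = load_image(ds_path, mpp)
    src, dst = load_landmarks(landmarks_path)
    run = analyze_pair(he, ds, src, dst, cfg)
    run.manifest.inputs = {
        "he": str(he_path),
        "ds": str(ds_path),
        "landmarks": str(landmarks_path),
        "mpp": mpp,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_report(run.candidate_results, out_dir / "report.csv", "csv", mpp=ds.mpp)
        write_report(run.candidate_results, out_dir / "report.json", "json", mpp=ds.mpp)
        run.manifest.write(out_dir / "manifest.json")
    return run


@dataclass
class HeatmapRun:
    labels: list
    grid_shape: tuple[int, int]
    heatmap: RasterImage
    manifest: RunManifest


def run_heatmap(
    he_path: str | Path,
    ds_path: str | Path,
    landmarks_path: str | Path,
    config: PipelineConfig | None = None,
    mpp: float = 0.5,
    out_dir: str | Path | None = None,
) -> HeatmapRun:
    """Tile the registered pair, label every tile, render the heatmap and
    export labelled tiles (when ``out_dir`` is given)."""
    cfg = config or PipelineConfig()
    he = load_image(he_path, mpp)
    ds = load_image(ds_path, mpp)
    src, dst = load_landmarks(landmarks_path)
    return heatmap_pair(he, ds, src, dst, cfg, out_dir=out_dir, inputs={
        "he": str(he_path), "ds": str(ds_path), "landmarks": str(landmarks_path), "mpp": mpp,
    })


def heatmap_pair(
    he: RasterImage,
    ds: RasterImage,
    landmarks_src: np.ndarray,
    landmarks_dst: np.ndarray,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    inputs: dict | None = None,
) -> HeatmapRun:
    cfg = config or PipelineConfig()
    manifest = RunManifest(inputs=inputs or {"mode": "in-memory"}, config=cfg.to_dict(), seed=cfg.random_seed)
    t0 = time.perf_counter()
    T = estimate_similarity(landmarks_src, landmarks_dst)
    he_reg = apply_transform(he, T, out_shape=ds.shape)
    tumor, ki67, both = _separate_stains(ds, cfg)
    labels, grid = label_tiles(he_reg, ds, tumor, both, cfg)
    heat = render_heatmap(labels, grid)
    manifest.timings_s["total"] = round(time.perf_counter() - t0, 3)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_image(heat, out_dir / "heatmap.png")
        export_labeled_tiles(ds, labels, out_dir / "tiles", he_registered=he_reg)
        manifest.write(out_dir / "manifest.json")
    return HeatmapRun(labels=labels, grid_shape=grid, heatmap=heat, manifest=manifest)


def run_same_field(
    he_field: RasterImage | str | Path,
    ds_field: RasterImage | str | Path,
    config: PipelineConfig | None = None,
    mpp: float = 0.5,
) -> KiIndexResult:
    """Grade a pre-cropped, pre-registered hot-spot field pair directly,
    skipping registration and hot-spot search."""
    cfg = config or PipelineConfig()
    if not isinstance(he_field, RasterImage):
        he_field = load_image(he_field, mpp)
    if not isinstance(ds_field, RasterImage):
        ds_field = load_image(ds_field, mpp)
    if he_field.shape != ds_field.shape:
        raise ValueError(f"field shapes differ: {he_field.shape} vs {ds_field.shape}")
    tumor, ki67, both = _separate_stains(ds_field, cfg)
    window = Window(0, 0, ds_field.shape[0], ds_field.shape[1])
    from .tiles import _tumor_mask_at_field

    tumor_field = _tumor_mask_at_field(tumor, window)
    d, _, _ = count_total_nuclei(he_field, tumor_field, cfg)
    if d == 0:
        return make_result(N=0, D=0, window=window, rank=1, config=cfg)
    pos_field = segment_ki67_field(ds_field, tumor_field, cfg)
    n = min(count_positive_nuclei(pos_field, window, cfg), d)
    return make_result(N=n, D=d, window=window, rank=1, config=cfg)
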