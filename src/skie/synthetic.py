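"""Synthetic paired-histology fixture generator with full ground truth.

Generates a triplet of co-registered synthetic images emulating the slide
material the pipeline targets:

* **DS** (double-stained): Permanent-Red tumor blobs, hematoxylin-blue
  Ki-67-negative nuclei, DAB-brown Ki-67-positive nuclei, white background;
* **SS** (single-stained): the same content without the red tumor stain;
* **H&E**: the same nucleus layout (all nuclei blue) over an eosin-pink
  tissue region, rendered in its own frame displaced by a known similarity
  transform, so registration has real work to do.

Images are synthesised as per-stain concentration fields in optical-density
space and converted to RGB through the configured stain vectors, which keeps
every pixel inside the deconvolution gamut. Every nucleus is recorded
(center, axes, tumor membership, Ki-67 status), so exact per-window counts,
the planted hot-spot and tile-level classes are all available as ground
truth. These are synthetic stand-ins: they exercise the pipeline's geometry
and counting logic, not tissue realism.

Ki-67 positivity is planted as an exact count: ``round(p_hot * n)`` of the
nuclei inside the hot-spot window (and ``round(p_bg * n)`` outside) are made
positive, so the planted hot-spot fraction equals ``p_hot`` up to rounding
rather than fluctuating binomially.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import PipelineConfig, RasterImage, Window, save_image
from .registration import SimilarityTransform
from .stain import od_to_rgb

# peak stain optical densities used by the renderer
_OD_NUCLEUS = 0.85
_OD_TUMOR_RED = 0.40
_OD_EOSIN_TISSUE = 0.30
_OD_TISSUE_WASH = 0.15  # hematoxylin counterstain over all tissue in DS/SS
_EDGE_PX = 1.5  # soft-edge width of a nucleus boundary


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture (defaults = benchmark conditions)."""

    size_px: int = 2000
    mpp: float = 0.5
    # geometry (DS frame, row/col px); semi-axes get a small per-seed jitter
    blob_center: tuple[float, float] = (1000.0, 1000.0)
    blob_axes: tuple[float, float] = (650.0, 700.0)
    tissue_axes: tuple[float, float] = (880.0, 920.0)
    # nuclei
    # GI-NET nuclei are characteristically monomorphic (uniform, round), so
    # the default size dispersion is small
    nucleus_radius_px: float = 8.0
    nucleus_radius_sd_px: float = 0.5
    nucleus_eccentricity: float = 0.12
    density_in_per_mm2: float = 4000.0
    density_out_per_mm2: float = 1000.0
    clump_fraction: float = 0.2
    n_distractor_positives: int = 40
    # Ki-67 positivity
    p_bg: float = 0.01
    p_hot: float = 0.05
    hotspot_origin: tuple[int, int] = (500, 500)
    hotspot_side_px: int = 1000
    # misalignment of the H&E frame (maps H&E xy -> DS xy)
    transform: SimilarityTransform = field(
        default_factory=lambda: SimilarityTransform(scale=1.015, rotation=0.04, tx=18.0, ty=-12.0)
    )
    n_landmarks: int = 10
    noise_sd: float = 1.5
    identical_nuclei: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_bg < 1.0 and 0.0 < self.p_hot <= 1.0 and self.p_bg < self.p_hot):
            raise ValueError("need 0 <= p_bg < p_hot <= 1")
        if self.density_in_per_mm2 < 0 or self.density_out_per_mm2 < 0:
            raise ValueError("densities must be >= 0")
        w = self.hotspot_window
        if not w.contained_in((self.size_px, self.size_px)):
            raise ValueError("hot-spot window must lie inside the image")

    @property
    def hotspot_window(self) -> Window:
        return Window(self.hotspot_origin[0], self.hotspot_origin[1], self.hotspot_side_px, self.hotspot_side_px)


@dataclass
class GroundTruth:
    """Complete record of the planted content (all in the DS frame)."""

    spec: FixtureSpec
    centers: np.ndarray  # (n, 2) row/col of every nucleus
    axes: np.ndarray  # (n, 2) semi-axes (a, b) px
    orientations: np.ndarray  # (n,) radians
    in_tumor: np.ndarray  # (n,) bool
    positive: np.ndarray  # (n,) bool
    transform: SimilarityTransform  # H&E -> DS
    landmarks_he: np.ndarray  # (m, 2) xy
    landmarks_ds: np.ndarray  # (m, 2) xy

    @property
    def hotspot_window(self) -> Window:
        return self.spec.hotspot_window

    def truth_counts(self, window: Window) -> tuple[int, int]:
        """(N_true, D_true): planted tumor nuclei (and the Ki-67-positive
        subset) whose centers fall inside the half-open window."""
        inside = (
            (self.centers[:, 0] >= window.row0)
            & (self.centers[:, 0] < window.row1)
            & (self.centers[:, 1] >= window.col0)
            & (self.centers[:, 1] < window.col1)
        )
        d = int(np.sum(inside & self.in_tumor))
        n = int(np.sum(inside & self.in_tumor & self.positive))
        return n, d

    def blob_mask(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        shape = shape or (self.spec.size_px, self.spec.size_px)
        return _ellipse_mask(shape, self.spec.blob_center, self._blob_axes_jittered())

    def tissue_mask(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        shape = shape or (self.spec.size_px, self.spec.size_px)
        return _ellipse_mask(shape, self.spec.blob_center, self._tissue_axes_jittered())

    def _blob_axes_jittered(self) -> tuple[float, float]:
        return _jittered_axes(self.spec, which="blob")

    def _tissue_axes_jittered(self) -> tuple[float, float]:
        return _jittered_axes(self.spec, which="tissue")

    def tile_classes(self, tile_px: int, config: PipelineConfig) -> np.ndarray:
        """True 4-class labels on the non-overlapping tile grid (remainders
        dropped), applying the same rules as the tile labeller to the planted
        geometry and counts: background > threshold -> 0, synaptophysin
        fraction < threshold -> 1, else tile Ki-67 index < t_g1g2 -> 2
        else -> 3."""
        size = self.spec.size_px
        n_r, n_c = size // tile_px, size // tile_px
        tissue = self.tissue_mask()
        blob = self.blob_mask()
        out = np.zeros((n_r, n_c), dtype=int)
        for i in range(n_r):
            for j in range(n_c):
                sl = (slice(i * tile_px, (i + 1) * tile_px), slice(j * tile_px, (j + 1) * tile_px))
                bg_frac = 1.0 - float(tissue[sl].mean())
                if bg_frac * 100.0 > config.tile_background_threshold:
                    out[i, j] = 0
                    continue
                syn_frac = float(blob[sl].mean())
                if syn_frac * 100.0 < config.tile_synaptophysin_threshold:
                    out[i, j] = 1
                    continue
                n, d = self.truth_counts(Window(i * tile_px, j * tile_px, tile_px, tile_px))
                if d == 0:
                    out[i, j] = 1
                    continue
                out[i, j] = 2 if 100.0 * n / d < config.t_g1g2 else 3
        return out

    def to_json(self, path: str | Path) -> None:
        data = {
            "spec": _spec_to_dict(self.spec),
            "centers": self.centers.tolist(),
            "axes": self.axes.tolist(),
            "orientations": self.orientations.tolist(),
            "in_tumor": self.in_tumor.astype(int).tolist(),
            "positive": self.positive.astype(int).tolist(),
            "transform": {
                "scale": self.transform.scale,
                "rotation": self.transform.rotation,
                "tx": self.transform.tx,
                "ty": self.transform.ty,
            },
            "landmarks_he": self.landmarks_he.tolist(),
            "landmarks_ds": self.landmarks_ds.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(data, fh)

    @staticmethod
    def from_json(path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        spec = _spec_from_dict(d["spec"])
        return GroundTruth(
            spec=spec,
            centers=np.asarray(d["centers"], dtype=float).reshape(-1, 2),
            axes=np.asarray(d["axes"], dtype=float).reshape(-1, 2),
            orientations=np.asarray(d["orientations"], dtype=float),
            in_tumor=np.asarray(d["in_tumor"], dtype=bool),
            positive=np.asarray(d["positive"], dtype=bool),
            transform=SimilarityTransform(**d["transform"]),
            landmarks_he=np.asarray(d["landmarks_he"], dtype=float).reshape(-1, 2),
            landmarks_ds=np.asarray(d["landmarks_ds"], dtype=float).reshape(-1, 2),
        )


def _spec_to_dict(spec: FixtureSpec) -> dict:
    t = spec.transform
    d = {
        k: getattr(spec, k)
        for k in (
            "size_px",
            "mpp",
            "blob_center",
            "blob_axes",
            "tissue_axes",
            "nucleus_radius_px",
            "nucleus_radius_sd_px",
            "nucleus_eccentricity",
            "density_in_per_mm2",
            "density_out_per_mm2",
            "clump_fraction",
            "n_distractor_positives",
            "p_bg",
            "p_hot",
            "hotspot_origin",
            "hotspot_side_px",
            "n_landmarks",
            "noise_sd",
            "identical_nuclei",
            "seed",
        )
    }
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
    d["transform"] = {"scale": t.scale, "rotation": t.rotation, "tx": t.tx, "ty": t.ty}
    return d


def _spec_from_dict(d: dict) -> FixtureSpec:
    d = dict(d)
    t = d.pop("transform")
    for k in ("blob_center", "blob_axes", "tissue_axes", "hotspot_origin"):
        d[k] = tuple(d[k])
    return FixtureSpec(transform=SimilarityTransform(**t), **d)


def _jittered_axes(spec: FixtureSpec, which: str) -> tuple[float, float]:
    """Per-seed +-3% jitter on the ellipse axes so fixtures differ in shape;
    derived deterministically from the seed, independent of draw order."""
    rng = np.random.default_rng(spec.seed * 7919 + (11 if which == "blob" else 13))
    base = spec.blob_axes if which == "blob" else spec.tissue_axes
    f = rng.uniform(0.97, 1.03, size=2)
    return (base[0] * f[0], base[1] * f[1])


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float], axes: tuple[float, float]) -> np.ndarray:
    rr, cc = np.ogrid[0 : shape[0], 0 : shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def _sample_in_ellipse(
    rng: np.random.Generator, n: int, center: tuple[float, float], axes: tuple[float, float], margin: float
) -> np.ndarray:
    """Uniform points inside the ellipse shrunk by ``margin`` px on each axis."""
    a, b = max(axes[0] - margin, 1.0), max(axes[1] - margin, 1.0)
    u = rng.uniform(0, 1, size=n)
    theta = rng.uniform(0, 2 * np.pi, size=n)
    r = np.sqrt(u)
    return np.column_stack([center[0] + r * a * np.cos(theta), center[1] + r * b * np.sin(theta)])


def _sample_in_annulus(
    rng: np.random.Generator,
    n: int,
    center: tuple[float, float],
    inner_axes: tuple[float, float],
    outer_axes: tuple[float, float],
    margin: float,
) -> np.ndarray:
    """Uniform-ish points inside the outer ellipse but outside the inner one."""
    out = []
    need = n
    for _ in range(200):
        if need <= 0:
            break
        cand = _sample_in_ellipse(rng, max(4 * need, 16), center, outer_axes, margin)
        norm = ((cand[:, 0] - center[0]) / (inner_axes[0] + margin)) ** 2 + (
            (cand[:, 1] - center[1]) / (inner_axes[1] + margin)
        ) ** 2
        keep = cand[norm > 1.0]
        out.append(keep[:need])
        need -= len(keep[:need])
    if need > 0:
        raise PlacementError("non-tumor tissue region too thin for the requested nucleus count")
    return np.concatenate(out, axis=0)


class PlacementError(RuntimeError):
    """Requested nucleus density exceeds what dart-throwing can pack."""


class _Placer:
    """Grid-accelerated dart throwing with a per-point hard-core radius.

    Points i and j are accepted only if their distance is at least
    ``rho_i + rho_j``: clump-pair sites carry a larger radius than single
    nuclei so partner nuclei of different pairs can never merge, while
    single-single spacing stays at the nucleus-disjointness minimum.
    """

    def __init__(self, cell: float):
        self.cell = cell
        self.grid: dict[tuple[int, int], list[int]] = {}
        self.pts: list[np.ndarray] = []
        self.rhos: list[float] = []
        self.max_rho = 0.0

    def try_add(self, p: np.ndarray, rho: float) -> bool:
        gi, gj = int(p[0] / self.cell), int(p[1] / self.cell)
        reach = int(np.ceil((rho + self.max_rho) / self.cell)) + 1
        for di in range(-reach, reach + 1):
            for dj in range(-reach, reach + 1):
                for idx in self.grid.get((gi + di, gj + dj), ()):
                    d = rho + self.rhos[idx]
                    q = self.pts[idx]
                    if (q[0] - p[0]) ** 2 + (q[1] - p[1]) ** 2 < d * d:
                        return False
        self.pts.append(np.asarray(p, dtype=float))
        self.rhos.append(rho)
        self.max_rho = max(self.max_rho, rho)
        self.grid.setdefault((gi, gj), []).append(len(self.pts) - 1)
        return True

    def throw(self, sampler, n_sites: int, rho: float, max_tries: int = 120) -> np.ndarray:
        placed: list[np.ndarray] = []
        if n_sites == 0:
            return np.zeros((0, 2))
        batch = max(n_sites, 256)
        for _ in range(max_tries):
            for p in sampler(batch):
                if self.try_add(p, rho):
                    placed.append(p)
                    if len(placed) == n_sites:
                        return np.asarray(placed).reshape(n_sites, 2)
        raise PlacementError(
            f"could only place {len(placed)}/{n_sites} nuclei at core radius {rho:.1f} px; density infeasible"
        )


def _paint_ellipse(
    conc: np.ndarray,
    center: tuple[float, float],
    a: float,
    b: float,
    phi: float,
    peak: float,
    edge_px: float,
) -> None:
    """Additively paint a soft-edged ellipse into a concentration field."""
    h, w = conc.shape
    extent = max(a, b) + edge_px + 1
    r0, r1 = max(0, int(center[0] - extent)), min(h, int(center[0] + extent) + 1)
    c0, c1 = max(0, int(center[1] - extent)), min(w, int(center[1] + extent) + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr, dc = rr - center[0], cc - center[1]
    u = dr * np.cos(phi) + dc * np.sin(phi)
    v = -dr * np.sin(phi) + dc * np.cos(phi)
    rnorm = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    # linear soft edge of physical width edge_px at the ellipse boundary
    ramp = np.clip((1.0 - rnorm) * min(a, b) / edge_px + 0.5, 0.0, 1.0)
    conc[r0:r1, c0:c1] += peak * ramp


def _render(
    shape: tuple[int, int],
    stain_fields: list[tuple[np.ndarray, tuple[float, float, float]]],
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    od = np.zeros((shape[0], shape[1], 3), dtype=np.float32)
    for conc, vec in stain_fields:
        v = np.asarray(vec, dtype=np.float32)
        v = v / np.linalg.norm(v)
        od += conc[..., None] * v[None, None, :]
    rgb = od_to_rgb(od).astype(np.float32)
    if noise_sd > 0:
        rgb = rgb + rng.normal(0.0, noise_sd, size=rgb.shape)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def _grid_landmarks(spec: FixtureSpec) -> np.ndarray:
    """n landmark points (xy, DS frame) on a jittered grid over the tissue."""
    rng = np.random.default_rng(spec.seed * 104729 + 17)
    n = spec.n_landmarks
    side = int(np.ceil(np.sqrt(n)))
    lo, hi = 0.15 * spec.size_px, 0.85 * spec.size_px
    xs = np.linspace(lo, hi, side)
    ys = np.linspace(lo, hi, side)
    pts = np.array([(x, y) for y in ys for x in xs])[:n]
    return pts + rng.uniform(-20, 20, size=pts.shape)


def generate_pair(spec: FixtureSpec, config: PipelineConfig | None = None):
    """Generate one fixture triplet.

    Returns
    -------
    (he, ds, ss, truth)
        ``he`` is rendered in its own (misaligned) frame; ``ds``/``ss`` share
        the reference frame. ``truth`` records every planted nucleus.
    """
    cfg = config or PipelineConfig()
    rng = np.random.default_rng(spec.seed)
    size = spec.size_px
    blob_axes = _jittered_axes(spec, "blob")
    tissue_axes = _jittered_axes(spec, "tissue")

    mm2_per_px2 = (spec.mpp / 1000.0) ** 2
    blob_area_mm2 = np.pi * blob_axes[0] * blob_axes[1] * mm2_per_px2
    tissue_area_mm2 = np.pi * tissue_axes[0] * tissue_axes[1] * mm2_per_px2
    n_in = int(round(spec.density_in_per_mm2 * blob_area_mm2))
    n_out = int(round(spec.density_out_per_mm2 * max(tissue_area_mm2 - blob_area_mm2, 0.0)))

    r_mean = spec.nucleus_radius_px
    min_sep = 2.0 * r_mean + 3.0

    centers_list: list[np.ndarray] = []
    tumor_flags: list[np.ndarray] = []

    def place(n_total: int, sampler, clump_fraction: float) -> np.ndarray:
        if n_total == 0:
            return np.zeros((0, 2))
        n_pairs = int(round(clump_fraction * n_total / 2.0))
        n_single = n_total - 2 * n_pairs
        placer = _Placer(cell=max(min_sep / (2.0 * np.sqrt(2.0)), 1.0))
        out = []
        if n_pairs:
            # pair sites first (larger clearance): partners sit 0.6 r from
            # the site, so the site's hard core grows by that much
            pair_sites = placer.throw(sampler, n_pairs, min_sep / 2.0 + 0.6 * r_mean)
            for base in pair_sites:
                ang = rng.uniform(0, 2 * np.pi)
                step = 0.6 * r_mean * np.array([np.cos(ang), np.sin(ang)])
                out.append(np.stack([base + step, base - step]))
        out.append(placer.throw(sampler, n_single, min_sep / 2.0))
        return np.concatenate(out, axis=0)

    margin = 2.0 * r_mean
    tumor_centers = place(
        n_in,
        lambda m: _sample_in_ellipse(rng, m, spec.blob_center, blob_axes, margin),
        spec.clump_fraction,
    )
    out_centers = place(
        n_out,
        lambda m: _sample_in_annulus(rng, m, spec.blob_center, blob_axes, tissue_axes, margin),
        0.0,
    )
    centers = np.concatenate([tumor_centers, out_centers], axis=0)
    in_tumor = np.concatenate(
        [np.ones(len(tumor_centers), dtype=bool), np.zeros(len(out_centers), dtype=bool)]
    )
    n_nuclei = len(centers)

    if spec.identical_nuclei:
        centers = np.rint(centers)
        radii = np.full(n_nuclei, r_mean)
        ecc = np.zeros(n_nuclei)
        orientations = np.zeros(n_nuclei)
    else:
        radii = np.clip(rng.normal(r_mean, spec.nucleus_radius_sd_px, size=n_nuclei), 0.5 * r_mean, 1.5 * r_mean)
        ecc = np.full(n_nuclei, spec.nucleus_eccentricity)
        orientations = rng.uniform(0, np.pi, size=n_nuclei)
    axes = np.column_stack([radii * (1 + ecc), radii / (1 + ecc)])

    positive = _assign_positivity(rng, spec, centers, in_tumor)

    # distractor Ki-67-positive nuclei outside the tumor (endothelium,
    # lymphocytes, background epithelium): they must be excluded by the
    # tumor-mask intersection, never counted.
    n_dist = min(spec.n_distractor_positives, int((~in_tumor).sum()))
    if n_dist > 0:
        idx_out = np.flatnonzero(~in_tumor)
        chosen = rng.choice(idx_out, size=n_dist, replace=False)
        positive[chosen] = True

    lm_ds = _grid_landmarks(spec)
    t_inv = spec.transform.inverse()
    lm_he = t_inv.apply(lm_ds)

    truth = GroundTruth(
        spec=spec,
        centers=centers,
        axes=axes,
        orientations=orientations,
        in_tumor=in_tumor,
        positive=positive,
        transform=spec.transform,
        landmarks_he=lm_he,
        landmarks_ds=lm_ds,
    )

    ds_img, ss_img = _render_ds_ss(spec, cfg, truth, blob_axes, rng)
    he_img = _render_he(spec, cfg, truth, tissue_axes, rng)
    return he_img, ds_img, ss_img, truth


def _assign_positivity(
    rng: np.random.Generator, spec: FixtureSpec, centers: np.ndarray, in_tumor: np.ndarray
) -> np.ndarray:
    """Plant exact positive counts inside/outside the hot-spot window and
    verify the planted window dominates every half-stride window; reshuffle
    (fresh draw) in the unlikely event it does not."""
    w = spec.hotspot_window
    inside_w = (
        (centers[:, 0] >= w.row0)
        & (centers[:, 0] < w.row1)
        & (centers[:, 1] >= w.col0)
        & (centers[:, 1] < w.col1)
    )
    idx_hot = np.flatnonzero(in_tumor & inside_w)
    idx_rest = np.flatnonzero(in_tumor & ~inside_w)
    n_hot = int(round(spec.p_hot * len(idx_hot)))
    n_rest = int(round(spec.p_bg * len(idx_rest)))
    for _ in range(8):
        positive = np.zeros(len(centers), dtype=bool)
        if n_hot:
            positive[rng.choice(idx_hot, size=n_hot, replace=False)] = True
        if n_rest:
            positive[rng.choice(idx_rest, size=n_rest, replace=False)] = True
        if _planted_window_is_max(spec, centers, in_tumor & positive):
            return positive
    return positive  # extremely unlikely; downstream brute-force checks will flag it


def _planted_window_is_max(spec: FixtureSpec, centers: np.ndarray, pos_mask: np.ndarray) -> bool:
    pts = centers[pos_mask]
    side = spec.hotspot_side_px
    stride = side // 2
    w = spec.hotspot_window
    planted = _count_in(pts, w.row0, w.col0, side)
    for r in range(0, spec.size_px - side + 1, stride):
        for c in range(0, spec.size_px - side + 1, stride):
            if (r, c) == (w.row0, w.col0):
                continue
            if _count_in(pts, r, c, side) > planted:
                return False
    return True


def _count_in(pts: np.ndarray, r: int, c: int, side: int) -> int:
    if len(pts) == 0:
        return 0
    return int(
        np.sum((pts[:, 0] >= r) & (pts[:, 0] < r + side) & (pts[:, 1] >= c) & (pts[:, 1] < c + side))
    )


def _render_ds_ss(spec, cfg, truth: GroundTruth, blob_axes, rng) -> tuple[RasterImage, RasterImage]:
    size = spec.size_px
    red = np.zeros((size, size), dtype=np.float32)
    _paint_ellipse(red, spec.blob_center, blob_axes[0], blob_axes[1], 0.0, _OD_TUMOR_RED, 3.0)
    hema = np.zeros((size, size), dtype=np.float32)
    # hematoxylin counterstain: all tissue is faintly blue on DS/SS sections
    tissue_axes = _jittered_axes(spec, "tissue")
    _paint_ellipse(hema, spec.blob_center, tissue_axes[0], tissue_axes[1], 0.0, _OD_TISSUE_WASH, 3.0)
    dab = np.zeros((size, size), dtype=np.float32)
    for i in range(len(truth.centers)):
        target = dab if truth.positive[i] else hema
        _paint_ellipse(
            target,
            tuple(truth.centers[i]),
            truth.axes[i, 0],
            truth.axes[i, 1],
            truth.orientations[i],
            _OD_NUCLEUS,
            _EDGE_PX if not spec.identical_nuclei else 0.75,
        )
    fields_ds = [(hema, cfg.od_hematoxylin), (dab, cfg.od_dab), (red, cfg.od_permanent_red)]
    fields_ss = [(hema, cfg.od_hematoxylin), (dab, cfg.od_dab)]
    noise_rng_ds = np.random.default_rng(spec.seed * 31 + 1)
    noise_rng_ss = np.random.default_rng(spec.seed * 31 + 2)
    ds = RasterImage(pixels=_render((size, size), fields_ds, spec.noise_sd, noise_rng_ds), mpp=spec.mpp)
    ss = RasterImage(pixels=_render((size, size), fields_ss, spec.noise_sd, noise_rng_ss), mpp=spec.mpp)
    return ds, ss


def _render_he(spec, cfg, truth: GroundTruth, tissue_axes, rng) -> RasterImage:
    """Render the H&E modality in its own frame: all content is mapped from
    the DS frame through the inverse of the misalignment transform."""
    size = spec.size_px
    t_inv = spec.transform.inverse()
    s_inv = t_inv.scale
    eosin = np.zeros((size, size), dtype=np.float32)
    center_xy = t_inv.apply(np.array([[spec.blob_center[1], spec.blob_center[0]]]))[0]
    center_rc = (center_xy[1], center_xy[0])
    # an axis-aligned ellipse maps to an ellipse rotated by -theta with scaled axes
    _paint_ellipse(
        eosin,
        center_rc,
        tissue_axes[0] * s_inv,
        tissue_axes[1] * s_inv,
        _rc_rotation(t_inv.rotation),
        _OD_EOSIN_TISSUE,
        3.0,
    )
    hema = np.zeros((size, size), dtype=np.float32)
    centers_xy = truth.centers[:, ::-1]  # (col=x, row=y)
    he_xy = t_inv.apply(centers_xy)
    he_rc = he_xy[:, ::-1]
    if spec.identical_nuclei:
        he_rc = np.rint(he_rc)
    for i in range(len(he_rc)):
        _paint_ellipse(
            hema,
            tuple(he_rc[i]),
            truth.axes[i, 0] * s_inv,
            truth.axes[i, 1] * s_inv,
            truth.orientations[i] + _rc_rotation(t_inv.rotation),
            _OD_NUCLEUS,
            _EDGE_PX if not spec.identical_nuclei else 0.75,
        )
    fields = [(hema, cfg.od_hematoxylin), (eosin, cfg.od_eosin)]
    noise_rng = np.random.default_rng(spec.seed * 31 + 3)
    return RasterImage(pixels=_render((size, size), fields, spec.noise_sd, noise_rng), mpp=spec.mpp)


def _rc_rotation(theta_xy: float) -> float:
    """A rotation by theta in xy coordinates appears as a rotation by -theta
    in (row, col) coordinates because the axis swap flips handedness."""
    return -theta_xy


def exactness_spec(seed: int = 0) -> FixtureSpec:
    """Fixture for the exactness limit of area-ratio counting: disjoint
    identical nuclei (no clumps, no size dispersion, integer centers, no
    noise, identity transform) on a whole-image field, so the estimated
    counts must equal the planted counts exactly."""
    return FixtureSpec(
        seed=seed,
        size_px=1000,
        blob_center=(500.0, 500.0),
        blob_axes=(430.0, 450.0),
        tissue_axes=(480.0, 492.0),
        hotspot_origin=(0, 0),
        hotspot_side_px=1000,
        clump_fraction=0.0,
        density_out_per_mm2=0.0,
        n_distractor_positives=0,
        identical_nuclei=True,
        noise_sd=0.0,
        transform=SimilarityTransform.identity(),
    )


def benchmark_specs(
    n: int = 20,
    size_px: int = 2000,
    clump_fraction: float = 0.2,
    p_hot: float = 0.05,
    p_bg: float = 0.01,
    identical_nuclei: bool = False,
    **overrides,
) -> list[FixtureSpec]:
    """The default benchmark: seeds 0..n-1 at the stated study conditions."""
    return [
        FixtureSpec(
            size_px=size_px,
            clump_fraction=clump_fraction,
            p_hot=p_hot,
            p_bg=p_bg,
            identical_nuclei=identical_nuclei,
            seed=s,
            **overrides,
        )
        for s in range(n)
    ]


def benchmark_suite(out_dir: str | Path, n: int = 20, config: PipelineConfig | None = None, **overrides) -> Path:
    """Write the n-fixture benchmark (PNG triplets, truth JSON, landmark CSVs
    and a manifest CSV) under ``out_dir``; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    rows = []
    for spec in benchmark_specs(n=n, **overrides):
        he, ds, ss, truth = generate_pair(spec, config)
        stem = f"fixture_{spec.seed:02d}"
        save_image(he, out_dir / f"{stem}_he.png")
        save_image(ds, out_dir / f"{stem}_ds.png")
        save_image(ss, out_dir / f"{stem}_ss.png")
        truth.to_json(out_dir / f"{stem}_truth.json")
        np.savetxt(
            out_dir / f"{stem}_landmarks.csv",
            np.column_stack([truth.landmarks_he, truth.landmarks_ds]),
            delimiter=",",
            header="x_he,y_he,x_ds,y_ds",
            comments="",
            fmt="%.6f",
        )
        n_true, d_true = truth.truth_counts(truth.hotspot_window)
        rows.append(
            {
                "seed": spec.seed,
                "he": f"{stem}_he.png",
                "ds": f"{stem}_ds.png",
                "ss": f"{stem}_ss.png",
                "truth": f"{stem}_truth.json",
                "landmarks": f"{stem}_landmarks.csv",
                "N_true": n_true,
                "D_true": d_true,
                "hotspot_row0": truth.hotspot_window.row0,
                "hotspot_col0": truth.hotspot_window.col0,
            }
        )
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    return manifest
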