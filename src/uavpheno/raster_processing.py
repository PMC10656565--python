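"""Height rasterization, multispectral-to-RGB co-registration, and per-plant
4-D image-stack extraction.

All rasters entering a stack must share one geotransform; the registration
step brings the coarser multispectral grid onto the RGB grid by an integer
phase-correlation shift applied to the geotransform followed by
nearest-neighbour resampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import xarray as xr
from scipy import ndimage

from .geo import BoundingBox, GeoTransform, RasterLayer

__all__ = [
    "PlantImageStack",
    "AlignmentReport",
    "rasterize_height",
    "subtract_surface",
    "phase_correlation_shift",
    "resample_nearest",
    "register_ms_to_rgb",
    "assess_alignment",
    "cut_plant_stack",
    "luminance",
]

#: Standard luminance weights for RGB -> grayscale conversion.
LUMINANCE_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class PlantImageStack:
    """Per-plant 4-D image stack ordered (time point, layer, row, col).

    ``mask`` is a per-time-point boolean validity mask of shape
    (n_tp, rows, cols); True marks vegetation/valid pixels.
    ``pixel_area_cm2`` is the ground area of one pixel.
    """

    values: np.ndarray
    tp_dat: List[int]
    layer_names: List[str]
    mask: Optional[np.ndarray] = None
    pixel_area_cm2: float = 1.0
    gt: Optional[GeoTransform] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError("stack values must be 4-D (tp, layer, row, col)")
        t, l, h, w = self.values.shape
        if t != len(self.tp_dat) or l != len(self.layer_names):
            raise ValueError("stack dimensions inconsistent with coordinates")
        if list(self.tp_dat) != sorted(set(self.tp_dat)):
            raise ValueError("tp_dat must be strictly increasing")
        if self.pixel_area_cm2 <= 0:
            raise ValueError("pixel_area_cm2 must be positive")
        if self.mask is None:
            self.mask = np.ones((t, h, w), dtype=bool)
        self.mask = np.asarray(self.mask)
        if self.mask.ndim == 2:
            self.mask = np.broadcast_to(self.mask, (t, h, w)).copy()
        if self.mask.shape != (t, h, w):
            raise ValueError("mask shape inconsistent with stack")

    @property
    def shape(self):
        return self.values.shape

    @property
    def pixel_size_m(self) -> float:
        return math.sqrt(self.pixel_area_cm2) / 100.0

    def tp_index(self, dat: int) -> int:
        return self.tp_dat.index(dat)

    def layer(self, dat: int, name: str) -> np.ndarray:
        """2-D view of one layer at one time point (by DAT and layer name)."""
        return self.values[self.tp_index(dat), self.layer_names.index(name)]

    def layers_at(self, dat: int) -> Dict[str, np.ndarray]:
        ti = self.tp_index(dat)
        return {n: self.values[ti, li] for li, n in enumerate(self.layer_names)}

    def to_xarray(self) -> xr.DataArray:
        return xr.DataArray(
            self.values,
            dims=("tp", "layer", "y", "x"),
            coords={"tp": self.tp_dat, "layer": self.layer_names},
            attrs={"pixel_area_cm2": self.pixel_area_cm2},
        )


@dataclass(frozen=True)
class AlignmentReport:
    """Spatial-accuracy QA between two co-located RGB acquisitions."""

    shift_px: Tuple[float, float]  # (dy, dx): row and column displacement
    shift_mm: Tuple[float, float]
    correlation: float


def rasterize_height(
    cloud: np.ndarray, gt: GeoTransform, shape: Tuple[int, int]
) -> RasterLayer:
    """Grid a point cloud to a height raster.

    Each cell takes the mean z of the points falling inside it; cells that
    receive no point are filled from their nearest filled neighbour.
    """
    cloud = np.asarray(cloud, dtype=float)
    if cloud.size == 0:
        raise ValueError("point cloud is empty")
    if cloud.ndim != 2 or cloud.shape[1] != 3:
        raise ValueError("point cloud must be an (n, 3) array of x, y, z")
    rows, cols = gt.xy_to_pixel(cloud[:, 0], cloud[:, 1])
    r = np.floor(rows).astype(int)
    c = np.floor(cols).astype(int)
    inb = (r >= 0) & (r < shape[0]) & (c >= 0) & (c < shape[1])
    if not inb.any():
        raise ValueError("no points fall inside the raster extent")
    r, c, z = r[inb], c[inb], cloud[inb, 2]

    sums = np.zeros(shape, dtype=float)
    counts = np.zeros(shape, dtype=float)
    np.add.at(sums, (r, c), z)
    np.add.at(counts, (r, c), 1.0)
    filled = counts > 0
    values = np.full(shape, np.nan)
    values[filled] = sums[filled] / counts[filled]

    if not filled.all():
        # nearest-neighbour fill from the populated cells
        _, idx = ndimage.distance_transform_edt(~filled, return_indices=True)
        values = values[idx[0], idx[1]]
    return RasterLayer(values=values, gt=gt, name="height")


def subtract_surface(height: RasterLayer, surface: RasterLayer) -> RasterLayer:
    """Plant height = height model minus the reference (first-flight) surface.

    Negative differences are clamped to zero so soil-level noise cannot
    produce negative canopy volume downstream.
    """
    if not height.same_geometry(surface):
        raise ValueError("height and surface rasters differ in geometry")
    diff = height.values - surface.values
    out = np.where(np.isnan(diff), np.nan, np.clip(diff, 0.0, None))
    return RasterLayer(values=out, gt=height.gt, name=height.name or "height")


def phase_correlation_shift(
    reference: np.ndarray, moving: np.ndarray
) -> Tuple[int, int]:
    """Integer translation between two images by phase cross-correlation.

    Returns (dy, dx) such that ``moving == np.roll(reference, (dy, dx),
    axis=(0, 1))`` for a pure cyclic translation. The peak of the inverse
    transform of the normalized cross-power spectrum is reported with
    wrap-around resolved to the interval (-N/2, N/2] on each axis.
    """
    a = np.asarray(reference, dtype=float)
    b = np.asarray(moving, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("images must be 2-D and share a shape")
    a = np.nan_to_num(a, nan=float(np.nanmean(a)))
    b = np.nan_to_num(b, nan=float(np.nanmean(b)))
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("phase correlation is undefined for a constant image")

    fa = np.fft.fft2(a)
    fb = np.fft.fft2(b)
    cross = fb * np.conj(fa)
    mag = np.abs(cross)
    cross = cross / np.maximum(mag, 1e-15)
    # peak of the magnitude: robust to contrast inversion between bands
    # (vegetation is bright in NIR but dark in visible luminance)
    corr = np.abs(np.fft.ifft2(cross))
    peak = np.unravel_index(int(np.argmax(corr)), corr.shape)

    shift = []
    for p, n in zip(peak, a.shape):
        s = int(p)
        if s > n // 2:
            s -= n
        shift.append(s)
    return shift[0], shift[1]


def resample_nearest(
    layer: RasterLayer, target_gt: GeoTransform, target_shape: Tuple[int, int]
) -> RasterLayer:
    """Nearest-neighbour resampling: each target cell center takes the value
    of the source cell that contains it; centers outside the source extent
    become missing."""
    xs, ys = target_gt.cell_centers(target_shape)
    rows, cols = layer.gt.xy_to_pixel(xs, ys)
    r = np.floor(rows).astype(int)
    c = np.floor(cols).astype(int)
    h, w = layer.shape
    inb = (r >= 0) & (r < h) & (c >= 0) & (c < w)
    if not inb.any():
        raise ValueError("source and target rasters do not overlap")
    out = np.full(target_shape, np.nan)
    out[inb] = layer.values[r[inb], c[inb]]
    return RasterLayer(values=out, gt=target_gt, name=layer.name)


def register_ms_to_rgb(
    ms: Sequence[RasterLayer],
    rgb_ref: RasterLayer,
    align_layer: str = "NIR",
) -> List[RasterLayer]:
    """Register multispectral layers onto the RGB grid.

    Alignment: the named MS band (NIR by default) is provisionally resampled
    to the RGB grid and its residual integer shift against the reference
    grayscale is estimated by phase correlation; the shift is absorbed into
    the MS geotransform. Resampling: every MS layer is then resampled onto
    the RGB grid by nearest-neighbour assignment. Output geometry equals the
    reference geometry.
    """
    ms = list(ms)
    if not ms:
        return []
    names = [l.name for l in ms]
    if align_layer in names:
        probe = ms[names.index(align_layer)]
    else:
        probe = ms[-1]
    provisional = resample_nearest(probe, rgb_ref.gt, rgb_ref.shape)
    dy, dx = phase_correlation_shift(rgb_ref.values, provisional.values)
    # The provisional image equals the reference rolled by (dy, dx): MS
    # content sits dy rows south and dx cols east of where its geotransform
    # claims, i.e. its true origin is west/north of the stated one.
    src_gt = ms[0].gt
    corrected = GeoTransform(
        origin_x=src_gt.origin_x - dx * rgb_ref.gt.gsd_x,
        origin_y=src_gt.origin_y + dy * rgb_ref.gt.gsd_y,
        gsd_x=src_gt.gsd_x,
        gsd_y=src_gt.gsd_y,
    )
    out = []
    for layer in ms:
        shifted = RasterLayer(values=layer.values, gt=corrected, name=layer.name)
        out.append(resample_nearest(shifted, rgb_ref.gt, rgb_ref.shape))
    return out


def luminance(r: np.ndarray, g: np.ndarray, b: np.ndarray) -> np.ndarray:
    wr, wg, wb = LUMINANCE_WEIGHTS
    return wr * np.asarray(r, float) + wg * np.asarray(g, float) + wb * np.asarray(b, float)


def assess_alignment(
    rgb_a: Sequence[RasterLayer], rgb_b: Sequence[RasterLayer]
) -> AlignmentReport:
    """QA between two RGB acquisitions of the same scene.

    Both triplets are converted to grayscale by standard luminance weights;
    the displacement is estimated by phase correlation and the similarity by
    the Pearson correlation of the flattened grayscales.
    """
    if len(rgb_a) != 3 or len(rgb_b) != 3:
        raise ValueError("expected three layers (R, G, B) per acquisition")
    if not rgb_a[0].same_geometry(rgb_b[0]):
        raise ValueError("acquisitions differ in geometry")
    ga = luminance(*(l.values for l in rgb_a))
    gb = luminance(*(l.values for l in rgb_b))
    dy, dx = phase_correlation_shift(ga, gb)
    gsd = rgb_a[0].gt
    valid = np.isfinite(ga) & np.isfinite(gb)
    r = float(np.corrcoef(ga[valid].ravel(), gb[valid].ravel())[0, 1])
    return AlignmentReport(
        shift_px=(dy, dx),
        shift_mm=(dy * gsd.gsd_y * 1000.0, dx * gsd.gsd_x * 1000.0),
        correlation=r,
    )


def cut_plant_stack(
    box: BoundingBox,
    layers_by_tp: Mapping[int, Sequence[RasterLayer]],
    tp_dat: Optional[Sequence[int]] = None,
) -> PlantImageStack:
    """Cut the same pixel window from every layer of every time point.

    The window is the smallest half-open pixel window covering ``box`` on the
    shared (post-registration) grid. The box must lie inside the raster
    extent at every time point.
    """
    if tp_dat is None:
        tp_dat = sorted(layers_by_tp)
    tp_dat = list(tp_dat)
    first_layers = list(layers_by_tp[tp_dat[0]])
    gt = first_layers[0].gt
    shape = first_layers[0].shape
    layer_names = [l.name for l in first_layers]

    c0 = math.floor((box.xmin - gt.origin_x) / gt.gsd_x)
    c1 = math.ceil((box.xmax - gt.origin_x) / gt.gsd_x)
    r0 = math.floor((gt.origin_y - box.ymax) / gt.gsd_y)
    r1 = math.ceil((gt.origin_y - box.ymin) / gt.gsd_y)
    if c0 < 0 or r0 < 0 or c1 > shape[1] or r1 > shape[0]:
        raise ValueError("bounding box extends outside the raster extent")

    values = np.empty((len(tp_dat), len(layer_names), r1 - r0, c1 - c0))
    for ti, dat in enumerate(tp_dat):
        layers = list(layers_by_tp[dat])
        if [l.name for l in layers] != layer_names:
            raise ValueError("layer names differ across time points")
        for li, layer in enumerate(layers):
            if layer.shape != shape or layer.gt != gt:
                raise ValueError("all layers must share one geometry")
            values[ti, li] = layer.values[r0:r1, c0:c1]

    window_gt = GeoTransform(
        origin_x=gt.origin_x + c0 * gt.gsd_x,
        origin_y=gt.origin_y - r0 * gt.gsd_y,
        gsd_x=gt.gsd_x,
        gsd_y=gt.gsd_y,
    )
    return PlantImageStack(
        values=values,
        tp_dat=tp_dat,
        layer_names=layer_names,
        pixel_area_cm2=gt.gsd_x * gt.gsd_y * 1e4,
        gt=window_gt,
    )
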