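"""Vegetation indices, correlated-index pruning, the three-stage noise-filter
cascade (k-means soil mask, contour area filter, RGB histogram equalization),
and per-plant centering/cropping.

Layer naming: RGB-camera channels are "R", "G", "B"; multispectral bands are
"blue", "green", "red", "red_edge", "NIR". Index names carry a "-RGB"/"-MS"
suffix where both camera variants exist.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from sklearn.cluster import KMeans

from .raster_processing import PlantImageStack

logger = logging.getLogger(__name__)

__all__ = [
    "MaskLayer",
    "VI_REGISTRY",
    "VI_ORDER",
    "compute_vi_image",
    "compute_vi",
    "prune_correlated_vis",
    "soil_mask_kmeans",
    "contour_filter",
    "equalize_rgb",
    "noise_filter_cascade",
    "center_and_crop",
]

RGB_LAYERS = ["R", "G", "B"]
MS_LAYERS = ["blue", "green", "red", "red_edge", "NIR"]


@dataclass
class MaskLayer:
    """Boolean validity mask over one plant window; True marks vegetation."""

    values: np.ndarray
    provenance: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-D")


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(np.broadcast(num, den).shape, np.nan)
    ok = np.asarray(den != 0) & np.isfinite(den) & np.isfinite(num)
    out[ok] = np.asarray(num, float)[ok] / np.asarray(den, float)[ok]
    return out


def _grvi(g, r):
    return _safe_ratio(g - r, g + r)


def _mgrvi(g, r):
    return _safe_ratio(g**2 - r**2, g**2 + r**2)


def _rgbvi(g, b, r):
    return _safe_ratio(g**2 - b * r, g**2 + b * r)


#: name -> (required layer names, elementwise formula)
VI_REGISTRY: Dict[str, Tuple[Tuple[str, ...], callable]] = {
    "GRVI-RGB": (("G", "R"), lambda L: _grvi(L["G"], L["R"])),
    "MGRVI-RGB": (("G", "R"), lambda L: _mgrvi(L["G"], L["R"])),
    "RGBVI-RGB": (("G", "B", "R"), lambda L: _rgbvi(L["G"], L["B"], L["R"])),
    "GRVI-MS": (("green", "red"), lambda L: _grvi(L["green"], L["red"])),
    "MGRVI-MS": (("green", "red"), lambda L: _mgrvi(L["green"], L["red"])),
    "RGBVI-MS": (
        ("green", "blue", "red"),
        lambda L: _rgbvi(L["green"], L["blue"], L["red"]),
    ),
    "GNDVI": (("NIR", "green"), lambda L: _grvi(L["NIR"], L["green"])),
    "NDRE": (("NIR", "red_edge"), lambda L: _grvi(L["NIR"], L["red_edge"])),
    "NDVI": (("NIR", "red"), lambda L: _grvi(L["NIR"], L["red"])),
    "RECI": (("NIR", "red_edge"), lambda L: _safe_ratio(L["NIR"], L["red_edge"]) - 1.0),
    "SAVI": (
        ("NIR", "red"),
        lambda L: _safe_ratio(L["NIR"] - L["red"], L["NIR"] + L["red"] + 0.5) * 1.5,
    ),
}

#: Frozen evaluation/pruning order: RGB-camera variants first, then MS.
VI_ORDER: List[str] = [
    "GRVI-RGB",
    "MGRVI-RGB",
    "RGBVI-RGB",
    "GRVI-MS",
    "MGRVI-MS",
    "RGBVI-MS",
    "GNDVI",
    "NDRE",
    "NDVI",
    "RECI",
    "SAVI",
]


def compute_vi_image(layers: Mapping[str, np.ndarray], name: str) -> np.ndarray:
    """Evaluate one vegetation index elementwise on a dict of band images.

    Cells whose denominator is zero become NaN.
    """
    if name not in VI_REGISTRY:
        raise KeyError(f"unknown vegetation index: {name!r}")
    required, fn = VI_REGISTRY[name]
    missing = [k for k in required if k not in layers]
    if missing:
        raise KeyError(f"{name} requires layers {missing} not present")
    arrays = {k: np.asarray(layers[k], dtype=float) for k in required}
    return fn(arrays)


def compute_vi(stack: PlantImageStack, name: str) -> np.ndarray:
    """Per-time-point index images for one plant stack: (n_tp, rows, cols)."""
    out = np.empty((len(stack.tp_dat),) + stack.values.shape[2:])
    for ti, dat in enumerate(stack.tp_dat):
        out[ti] = compute_vi_image(stack.layers_at(dat), name)
    return out


def prune_correlated_vis(
    vi_table: pd.DataFrame,
    r_threshold: float = 0.95,
    order: Optional[Sequence[str]] = None,
) -> List[str]:
    """Greedy pruning of highly correlated indices.

    Walking the columns in the frozen registry order (RGB variants before
    MS), an index is dropped when its absolute Pearson correlation with any
    already-retained index exceeds ``r_threshold``. Constant columns have
    undefined correlations; they are retained and flagged via logging.
    """
    if len(vi_table) < 2:
        raise ValueError("need at least two rows to compute correlations")
    if order is None:
        order = [n for n in VI_ORDER if n in vi_table.columns]
        order += [c for c in vi_table.columns if c not in order]
    retained: List[str] = []
    for name in order:
        col = vi_table[name].to_numpy(dtype=float)
        if np.nanstd(col) == 0:
            logger.warning("VI %s is constant; correlation undefined, retained", name)
            retained.append(name)
            continue
        drop = False
        for kept in retained:
            other = vi_table[kept].to_numpy(dtype=float)
            if np.nanstd(other) == 0:
                continue
            ok = np.isfinite(col) & np.isfinite(other)
            if ok.sum() < 2:
                continue
            r = np.corrcoef(col[ok], other[ok])[0, 1]
            if abs(r) > r_threshold:
                drop = True
                break
        if not drop:
            retained.append(name)
    return retained


def soil_mask_kmeans(
    vi_images: Mapping[str, np.ndarray],
    ndvi: np.ndarray,
    seed: int = 0,
) -> MaskLayer:
    """Two-cluster k-means soil mask from per-pixel vegetation-index vectors.

    Pixels are clustered on their index vectors (k-means++ init, 10
    restarts, fixed seed); the cluster with the lower mean NDVI is labelled
    soil regardless of cluster index. The returned mask is True on
    vegetation. Pixels with any non-finite index value are masked out.
    """
    names = list(vi_images)
    arrays = [np.asarray(vi_images[n], dtype=float) for n in names]
    shape = arrays[0].shape
    X = np.stack([a.ravel() for a in arrays], axis=1)
    ndvi = np.asarray(ndvi, dtype=float).ravel()
    finite = np.isfinite(X).all(axis=1) & np.isfinite(ndvi)
    if np.unique(X[finite], axis=0).shape[0] < 2:
        raise ValueError("all pixels identical; k-means mask undefined")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict(X[finite])
    mean_ndvi = [ndvi[finite][labels == k].mean() for k in (0, 1)]
    veg_cluster = int(np.argmax(mean_ndvi))
    mask = np.zeros(X.shape[0], dtype=bool)
    mask[finite] = labels == veg_cluster
    return MaskLayer(values=mask.reshape(shape), provenance=("kmeans_soil",))


def contour_filter(mask: MaskLayer, min_area_fraction: float = 0.05) -> MaskLayer:
    """Remove small connected components of the vegetation mask.

    Components (8-connectivity) whose pixel area is below
    ``min_area_fraction`` of the largest component are removed. An empty
    mask passes through empty.
    """
    values = mask.values
    labeled, n = ndimage.label(values, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return MaskLayer(values=values.copy(),
                         provenance=mask.provenance + ("contour",))
    areas = ndimage.sum_labels(np.ones_like(values, dtype=float), labeled,
                               index=np.arange(1, n + 1))
    keep = areas >= min_area_fraction * areas.max()
    out = np.zeros_like(values)
    for lab in np.nonzero(keep)[0] + 1:
        out |= labeled == lab
    return MaskLayer(values=out, provenance=mask.provenance + ("contour",))


def equalize_rgb(rgb_layers: np.ndarray) -> np.ndarray:
    """Standard histogram equalization, applied independently per channel.

    Values are mapped onto a 256-level scale (inputs in [0, 1] are scaled by
    255 first), then each level v is remapped to round(255 * cdf(v)). NaNs
    are preserved. The output is on the 0..255 scale.
    """
    rgb = np.asarray(rgb_layers, dtype=float)
    out = np.full_like(rgb, np.nan)
    for ci in range(rgb.shape[0]):
        layer = rgb[ci]
        finite = np.isfinite(layer)
        if not finite.any():
            continue
        vals = layer[finite]
        if np.nanmax(np.abs(vals)) <= 1.0:
            vals = vals * 255.0
        levels = np.clip(np.rint(vals), 0, 255).astype(int)
        hist = np.bincount(levels, minlength=256)
        cdf = np.cumsum(hist) / levels.size
        mapped = np.rint(255.0 * cdf[levels])
        res = np.full(layer.shape, np.nan)
        res[finite] = mapped
        out[ci] = res
    return out


def noise_filter_cascade(
    stack: PlantImageStack,
    vi_names: Sequence[str],
    seed: int = 0,
    min_area_fraction: float = 0.05,
    separation: float = 4.0,
) -> List[MaskLayer]:
    """Soil mask + contour filter for every time point of a plant stack.

    For each time point the named indices are computed on the window, the
    two-cluster soil mask is derived and small components are removed.

    A separability guard makes the cascade idempotent: the lower-NDVI
    cluster is treated as soil only when the between-cluster NDVI gap
    exceeds ``separation`` times the pooled within-cluster NDVI standard
    deviation. Without the guard, rerunning the cascade on an already
    soil-free window would split the vegetation itself and remove half of
    it; a forced 2-means split of one homogeneous population yields a gap
    of about 2.7 pooled SDs, while genuine soil/vegetation contrast is far
    larger.
    """
    masks: List[MaskLayer] = []
    for ti, dat in enumerate(stack.tp_dat):
        layers = stack.layers_at(dat)
        prior = stack.mask[ti]
        vi_imgs = {n: compute_vi_image(layers, n) for n in vi_names}
        ndvi = compute_vi_image(layers, "NDVI")
        for img in vi_imgs.values():
            img[~prior] = np.nan
        ndvi_masked = np.where(prior, ndvi, np.nan)
        try:
            km_mask = soil_mask_kmeans(vi_imgs, ndvi_masked, seed=seed)
        except ValueError:
            masks.append(MaskLayer(prior & np.isfinite(ndvi),
                                   provenance=("degenerate",)))
            continue
        veg = km_mask.values
        soil = prior & np.isfinite(ndvi) & ~veg
        if soil.any() and veg.any():
            gap = abs(np.nanmean(ndvi[veg]) - np.nanmean(ndvi[soil]))
            pooled = math.sqrt(
                (np.nanvar(ndvi[veg]) + np.nanvar(ndvi[soil])) / 2.0
            )
            if pooled > 0 and gap <= separation * pooled:
                # clusters not separable: treat the whole window as vegetation
                veg = prior & np.isfinite(ndvi)
        filtered = contour_filter(
            MaskLayer(veg, provenance=("kmeans_soil",)),
            min_area_fraction=min_area_fraction,
        )
        masks.append(filtered)
    return masks


def _integer_translate(arr: np.ndarray, dy: int, dx: int, fill) -> np.ndarray:
    """Shift a 2-D array by whole pixels, filling vacated cells."""
    out = np.full_like(arr, fill)
    h, w = arr.shape
    src_r = slice(max(0, -dy), min(h, h - dy))
    src_c = slice(max(0, -dx), min(w, w - dx))
    dst_r = slice(max(0, dy), min(h, h + dy))
    dst_c = slice(max(0, dx), min(w, w + dx))
    out[dst_r, dst_c] = arr[src_r, src_c]
    return out


def hull_center(mask: np.ndarray) -> Tuple[float, float]:
    """Geometric center (row, col) of the convex hull of the True pixels,
    computed as the mean of the hull vertices. Degenerate point sets
    (collinear or fewer than three points) fall back to the pixel mean."""
    pts = np.argwhere(mask)
    if pts.size == 0:
        raise ValueError("mask is empty; cannot compute a convex hull")
    try:
        hull = ConvexHull(pts.astype(float))
        verts = pts[hull.vertices]
    except QhullError:
        verts = pts
    center = verts.mean(axis=0)
    return float(center[0]), float(center[1])


def center_and_crop(
    stack: PlantImageStack,
    first_tp_mask: Optional[MaskLayer] = None,
    crop_fraction: float = 0.70,
) -> PlantImageStack:
    """Center every layer of every time point on the plant and crop.

    The convex hull of the first-time-point vegetation mask defines the
    plant center (mean of hull vertices); all layers and masks are shifted
    by the same whole-pixel translation so this center lands on the window
    center, then a centered window of ``crop_fraction`` of each dimension
    is retained. Vacated cells are missing (False in masks).
    """
    if not (0 < crop_fraction <= 1):
        raise ValueError("crop_fraction must be in (0, 1]")
    mask0 = first_tp_mask.values if first_tp_mask is not None else stack.mask[0]
    cy, cx = hull_center(mask0)
    t, l, h, w = stack.values.shape
    target = ((h - 1) / 2.0, (w - 1) / 2.0)
    dy = int(round(target[0] - cy))
    dx = int(round(target[1] - cx))

    values = np.empty_like(stack.values)
    mask = np.zeros_like(stack.mask)
    for ti in range(t):
        for li in range(l):
            values[ti, li] = _integer_translate(stack.values[ti, li], dy, dx, np.nan)
        mask[ti] = _integer_translate(stack.mask[ti], dy, dx, False)

    out_h = int(round(crop_fraction * h))
    out_w = int(round(crop_fraction * w))
    r0 = (h - out_h) // 2
    c0 = (w - out_w) // 2
    return PlantImageStack(
        values=values[:, :, r0 : r0 + out_h, c0 : c0 + out_w],
        tp_dat=list(stack.tp_dat),
        layer_names=list(stack.layer_names),
        mask=mask[:, r0 : r0 + out_h, c0 : c0 + out_w],
        pixel_area_cm2=stack.pixel_area_cm2,
        gt=None,
    )
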