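"""Per-plant, per-time-point feature summarization and feature-table assembly.

Each plant's filtered image stack collapses to three groups of features per
time point: medians of the raw camera layers (level 1), medians of the
retained vegetation indices (level 2), and three canopy-geometry features
from the plant-height image (level 3): the 90th-percentile plant height, an
aggregate leaf angle, and the canopy volume

    volume = sum_i H_i * a_p          (heights in cm, pixel area a_p in cm^2)

where the leaf angle of a pixel is the angle between the vector from the
window center on the ground plane to the pixel's canopy surface point and
the vertical unit vector.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .plant_imaging import MS_LAYERS, RGB_LAYERS, compute_vi_image, equalize_rgb
from .raster_processing import PlantImageStack

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "layer_median",
    "plant_height_feature",
    "leaf_angle",
    "volume",
    "assemble_feature_table",
    "standardize",
]


@dataclass
class FeatureTable:
    """Plants x (time point x feature) matrix plus harvest weights.

    ``data`` is wide with columns named ``{feature}@{DAT}`` indexed by
    plant id; ``weights`` holds harvest weight (g/plant). After
    :func:`standardize`, ``scaler_mean``/``scaler_sd`` hold the training
    statistics for the inverse transform.
    """

    data: pd.DataFrame
    weights: pd.Series
    scaler_mean: Optional[pd.Series] = None
    scaler_sd: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise ValueError("duplicated (feature, tp) column in table")
        if (self.weights.dropna() <= 0).any():
            raise ValueError("harvest weights must be positive")

    @property
    def tp_dats(self) -> List[int]:
        return sorted({int(c.rsplit("@", 1)[1]) for c in self.data.columns})

    def columns_at(self, dats: Sequence[int]) -> List[str]:
        wanted = set(int(d) for d in dats)
        return [c for c in self.data.columns if int(c.rsplit("@", 1)[1]) in wanted]


def _masked_values(layer: np.ndarray, mask: Optional[np.ndarray]) -> np.ndarray:
    layer = np.asarray(layer, dtype=float)
    if mask is None:
        sel = np.ones(layer.shape, dtype=bool)
    else:
        sel = np.asarray(mask, dtype=bool)
    vals = layer[sel]
    return vals[np.isfinite(vals)]


def layer_median(layer: np.ndarray, mask: Optional[np.ndarray] = None) -> float:
    """Median over unmasked, non-missing cells (NaN when none remain)."""
    vals = _masked_values(layer, mask)
    if vals.size == 0:
        return float("nan")
    return float(np.median(vals))


def plant_height_feature(
    height_image: np.ndarray, mask: Optional[np.ndarray] = None
) -> float:
    """90th percentile of the plant-height image over unmasked cells,
    with linear interpolation between order statistics."""
    vals = _masked_values(height_image, mask)
    if vals.size == 0:
        return float("nan")
    return float(np.percentile(vals, 90, method="linear"))


def leaf_angle(
    height_image: np.ndarray,
    mask: Optional[np.ndarray] = None,
    plant_center: Optional[Tuple[float, float]] = None,
    pixel_size: float = 1.0,
) -> float:
    """Aggregate (median) per-pixel leaf angle in degrees.

    For each unmasked pixel p the vector P_p = (x_p - x_c, y_p - y_c, H_p)
    runs from the window center anchored on the ground plane to the canopy
    surface; its angle against the vertical unit vector V_c = (0, 0, 1) is
    arccos(P_p . V_c / ||P_p||). In-plane offsets are expressed in the same
    length unit as the heights via ``pixel_size``. Pixels with a zero vector
    (the center pixel at zero height) are excluded.
    """
    H = np.asarray(height_image, dtype=float)
    if mask is None:
        sel = np.ones(H.shape, dtype=bool)
    else:
        sel = np.asarray(mask, dtype=bool)
    sel = sel & np.isfinite(H)
    if plant_center is None:
        plant_center = ((H.shape[0] - 1) / 2.0, (H.shape[1] - 1) / 2.0)
    rr, cc = np.nonzero(sel)
    dy = (rr - plant_center[0]) * pixel_size
    dx = (cc - plant_center[1]) * pixel_size
    hz = H[rr, cc]
    norm = np.sqrt(dx**2 + dy**2 + hz**2)
    ok = norm > 0
    if not ok.any():
        return float("nan")
    cosang = np.clip(hz[ok] / norm[ok], -1.0, 1.0)
    return float(np.degrees(np.median(np.arccos(cosang))))


def volume(
    height_image_cm: np.ndarray,
    mask: Optional[np.ndarray] = None,
    pixel_area_cm2: float = 1.0,
) -> float:
    """Canopy volume in cm^3: sum of unmasked pixel heights (cm) times the
    pixel ground area (cm^2)."""
    if pixel_area_cm2 <= 0:
        raise ValueError("pixel_area_cm2 must be positive")
    vals = _masked_values(height_image_cm, mask)
    return float(vals.sum() * pixel_area_cm2)


def features_for_stack(
    stack: PlantImageStack,
    retained_vis: Sequence[str],
    height_layer: str = "height",
    equalize: bool = True,
) -> pd.DataFrame:
    """Long-form feature rows (one per time point) for a single plant stack.

    RGB medians are taken after histogram equalization (the third noise
    filter applies to the RGB layers only); MS and index medians use the
    raw reflectances; level-3 features come from the height layer in metres,
    converted to cm for the volume.
    """
    rows = []
    pixel_size_m = stack.pixel_size_m
    for ti, dat in enumerate(stack.tp_dat):
        layers = stack.layers_at(dat)
        mask = stack.mask[ti]
        feats: Dict[str, float] = {}

        rgb = np.stack([layers[n] for n in RGB_LAYERS])
        rgb_eq = equalize_rgb(rgb) if equalize else rgb
        for i, n in enumerate(RGB_LAYERS):
            feats[n] = layer_median(rgb_eq[i], mask)
        for n in MS_LAYERS:
            feats[n] = layer_median(layers[n], mask)
        for n in retained_vis:
            feats[n] = layer_median(compute_vi_image(layers, n), mask)

        height_m = layers[height_layer]
        feats["PH"] = plant_height_feature(height_m, mask)
        feats["leaf_angle"] = leaf_angle(height_m, mask, pixel_size=pixel_size_m)
        feats["volume"] = volume(height_m * 100.0, mask, stack.pixel_area_cm2)
        rows.append({"tp_dat": dat, **feats})
    return pd.DataFrame(rows)


def assemble_feature_table(
    stacks: Mapping[int, PlantImageStack],
    retained_vis: Sequence[str],
    weights: Mapping[int, float],
    height_layer: str = "height",
    equalize: bool = True,
) -> FeatureTable:
    """Build the wide plants x (feature@DAT) table with harvest weights.

    Plants lacking a stack (missed by the detector) are simply absent;
    weights for such plants are logged and dropped.
    """
    wide_rows = {}
    for plant_id, stack in stacks.items():
        long = features_for_stack(
            stack, retained_vis, height_layer=height_layer, equalize=equalize
        )
        row = {}
        for _, rec in long.iterrows():
            dat = int(rec["tp_dat"])
            for feat, val in rec.drop("tp_dat").items():
                row[f"{feat}@{dat}"] = float(val)
        wide_rows[plant_id] = row

    data = pd.DataFrame.from_dict(wide_rows, orient="index").sort_index()
    dropped = [pid for pid in weights if pid not in wide_rows]
    if dropped:
        logger.info("dropping weights for %d plants with no features", len(dropped))
    w = pd.Series(
        {pid: float(weights[pid]) for pid in wide_rows if pid in weights},
        dtype=float,
    ).reindex(data.index)
    return FeatureTable(data=data, weights=w)


def standardize(table: FeatureTable, fit_rows: Sequence) -> FeatureTable:
    """Z-score every column using mean/SD computed on ``fit_rows`` only.

    The population SD (ddof=0) is used; a zero-SD column raises an error
    naming the column. The fitted statistics are stored on the returned
    table for the inverse transform and for transforming held-out rows.
    """
    fit_rows = list(fit_rows)
    if not fit_rows:
        raise ValueError("fit_rows must be non-empty")
    fit = table.data.loc[fit_rows]
    mean = fit.mean(axis=0)
    sd = fit.std(axis=0, ddof=0)
    bad = sd.index[(sd == 0) | sd.isna()]
    if len(bad):
        raise ValueError(f"zero-SD column(s) on fit rows: {list(bad)}")
    data = (table.data - mean) / sd
    return FeatureTable(
        data=data,
        weights=table.weights.copy(),
        scaler_mean=mean,
        scaler_sd=sd,
    )
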