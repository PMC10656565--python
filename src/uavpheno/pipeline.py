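"""End-to-end orchestration: detections -> merged boxes -> grid assignment ->
per-plant stacks -> filter cascade -> centered/cropped stacks -> feature table.

This is the glue that the command-line interface and the acceptance
experiments drive; each step is a public function of its own module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .geo import BoundingBox, RasterLayer
from .phenotype_features import FeatureTable, assemble_feature_table, layer_median
from .plant_geolocation import (
    PlantAssignment,
    assign_boxes_to_grid,
    detection_accuracy,
    merge_detections,
)
from .plant_imaging import (
    MS_LAYERS,
    RGB_LAYERS,
    VI_ORDER,
    center_and_crop,
    compute_vi_image,
    noise_filter_cascade,
    prune_correlated_vis,
)
from .raster_processing import (
    PlantImageStack,
    cut_plant_stack,
    luminance,
    register_ms_to_rgb,
    subtract_surface,
)
from .synthetic_field import SyntheticFieldBundle

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "extract_feature_table"]


@dataclass
class PipelineResult:
    table: FeatureTable
    assignments: List[PlantAssignment]
    detection_accuracy: float
    retained_vis: List[str]
    merged_boxes: List[BoundingBox]


def _padded(box: BoundingBox, crop_fraction: float) -> BoundingBox:
    """Pad a box so that the post-centering central crop returns a field of
    view equal to the detected box (pad = (1/crop - 1)/2 per side)."""
    pad = (1.0 / crop_fraction - 1.0) / 2.0
    return box.padded(pad * box.width, pad * box.height)


def extract_feature_table(
    bundle: SyntheticFieldBundle,
    seed: int = 0,
    crop_fraction: float = 0.70,
    r_threshold: float = 0.95,
    min_area_fraction: float = 0.05,
    overlap_threshold: float = 0.40,
    max_dist_m: float = 0.45,
    register: bool = True,
) -> PipelineResult:
    """Run the full image-processing pipeline on a field bundle.

    Returns the standardizable feature table (plants x feature@DAT, with
    harvest weights), the grid assignments and the retained index set.
    """
    tps = bundle.tp_dat

    # 1. consolidate detections and index them to the sowing grid
    all_boxes = [b for dat in tps for b in bundle.detections.get(dat, [])]
    merged = merge_detections(all_boxes, overlap_threshold=overlap_threshold)
    assignments = assign_boxes_to_grid(bundle.grid, merged, max_dist_m=max_dist_m)
    accuracy = detection_accuracy(assignments, bundle.n_plants)

    # 2. canopy height (surface reference = first flight) and MS registration
    surface = bundle.layers(tps[0], ["height"])[0]
    layers_by_tp: Dict[int, List[RasterLayer]] = {}
    for dat in tps:
        rgb = bundle.layers(dat, RGB_LAYERS)
        ms = bundle.layers(dat, MS_LAYERS)
        if register:
            ref = RasterLayer(
                values=luminance(*(l.values for l in rgb)), gt=rgb[0].gt, name="lum"
            )
            ms = register_ms_to_rgb(ms, ref)
        canopy = subtract_surface(bundle.layers(dat, ["height"])[0], surface)
        layers_by_tp[dat] = rgb + ms + [canopy]

    # 3. per-plant stacks on padded windows
    stacks: Dict[int, PlantImageStack] = {}
    for a in assignments:
        if a.box is None:
            continue
        stacks[a.plant_id] = cut_plant_stack(
            _padded(a.box, crop_fraction), layers_by_tp, tp_dat=tps
        )

    if not stacks:
        raise ValueError("no plants were assigned; cannot build a feature table")

    # 4. prune correlated indices on the plants x TP median table (raw windows)
    vi_rows = []
    for pid, stack in stacks.items():
        for dat in tps:
            layers = stack.layers_at(dat)
            vi_rows.append(
                {name: layer_median(compute_vi_image(layers, name))
                 for name in VI_ORDER}
            )
    retained = prune_correlated_vis(pd.DataFrame(vi_rows), r_threshold=r_threshold)

    # 5. noise-filter cascade, centering and cropping
    processed: Dict[int, PlantImageStack] = {}
    for pid, stack in stacks.items():
        masks = noise_filter_cascade(
            stack, retained, seed=seed, min_area_fraction=min_area_fraction
        )
        stack.mask = np.stack([m.values for m in masks])
        processed[pid] = center_and_crop(stack, crop_fraction=crop_fraction)

    # 6. features and weights
    weights = dict(
        zip(bundle.truth["plant_id"].astype(int), bundle.truth["weight_g"])
    )
    table = assemble_feature_table(processed, retained, weights)
    return PipelineResult(
        table=table,
        assignments=assignments,
        detection_accuracy=accuracy,
        retained_vis=retained,
        merged_boxes=merged,
    )
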