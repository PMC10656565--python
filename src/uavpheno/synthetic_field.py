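"""Synthetic field generator with known ground truth.

Emulates a UAV phenotyping campaign over a row-crop field (sowing grid of
0.45 m x 0.65 m), producing for each flight date the three raster sources
(RGB 3-band, multispectral 5-band, plant height), detector output with a
configurable miss rate and box jitter, the sowing grid, and a per-plant truth
table with harvest weights.

Plants are rendered as uniform-reflectance discs with a cosine-tapered height
profile; radius and height follow a logistic growth curve with a per-plant
lognormal vigor effect. Multispectral red carries a per-plant chlorophyll
factor expressed only through a mid-season Gaussian bump, so a plant's
spectral contribution to its harvest weight is observable in mid-season
flights but not in the final one. True weights follow

    weight_i = beta_volume * V_i(final) + beta_spectral * NDVI_i(mid) + eps_i

where V_i and the mean NDVI are computed from the *rendered* rasters (not
from the analytic profile), so regenerating the features from the emitted
imagery reproduces the weights exactly when the noise is off.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as uio
from .geo import BoundingBox, GeoTransform, RasterLayer
from .phenotype_features import volume as canopy_volume
from .plant_geolocation import GridPoint, build_grid

__all__ = [
    "GrowthParams",
    "WeightModelParams",
    "DetectorParams",
    "FieldConfig",
    "SyntheticFieldBundle",
    "generate_field",
    "simulate_detections",
    "write_bundle",
    "read_bundle",
]

RGB_LAYERS = ["R", "G", "B"]
MS_LAYERS = ["blue", "green", "red", "red_edge", "NIR"]
ALL_LAYERS = RGB_LAYERS + MS_LAYERS + ["height"]

#: Endmember reflectances. Vegetation/soil NIR-red contrast is strong enough
#: that a 2-means soil mask on vegetation indices must separate them.
VEG_REFLECTANCE = {
    "R": 0.10, "G": 0.35, "B": 0.08,
    "blue": 0.05, "green": 0.12, "red": 0.12, "red_edge": 0.35, "NIR": 0.80,
}
SOIL_REFLECTANCE = {
    "R": 0.35, "G": 0.30, "B": 0.22,
    "blue": 0.18, "green": 0.22, "red": 0.30, "red_edge": 0.27, "NIR": 0.25,
}

REFLECTANCE_SCALE = 10000.0  # integer scaling for on-disk reflectance


@dataclass(frozen=True)
class GrowthParams:
    """Logistic canopy growth with a multiplicative lognormal plant effect.

    Radius scales as vigor^0.5 and height as vigor^2, so canopy volume scales
    roughly as vigor^3; with ``plant_sigma`` = 0.18 this yields a volume CV
    near 0.6, comparable to field-grown heading vegetables.
    """

    max_radius_m: float = 0.17
    max_height_m: float = 0.25
    rate: float = 0.12  # per day
    midpoint_dat: float = 55.0
    seedling_radius_m: float = 0.04
    seedling_height_m: float = 0.03
    plant_sigma: float = 0.18


@dataclass(frozen=True)
class WeightModelParams:
    """Linear truth model for harvest weight (g/plant).

    Defaults give a weight distribution with mean near 2850 g and SD near
    900 g across a default field.
    """

    beta_volume: float = 0.125  # g per cm^3 of final canopy volume
    beta_spectral: float = 1800.0  # g per unit of mid-season mean NDVI
    noise_sd: float = 80.0  # g


@dataclass(frozen=True)
class DetectorParams:
    """Detector emulation: independent per-plant misses and edge jitter."""

    miss_rate: float = 0.05
    jitter_sd_m: float = 0.01


@dataclass(frozen=True)
class FieldConfig:
    n_rows: int = 10
    n_cols: int = 10
    plant_spacing_m: float = 0.45
    row_spacing_m: float = 0.65
    gsd_m: float = 0.01
    timepoints_dat: Tuple[int, ...] = (12, 26, 40, 54, 68, 80, 90, 101)
    growth: GrowthParams = field(default_factory=GrowthParams)
    weight_model: WeightModelParams = field(default_factory=WeightModelParams)
    detector: DetectorParams = field(default_factory=DetectorParams)
    seed: int = 0
    margin_m: float = 0.5  # raster margin beyond the outermost plants
    pixel_noise_sd: float = 0.01  # additive reflectance noise, all bands
    spectral_sigma: float = 0.35  # lognormal sigma of the chlorophyll factor
    bump_width_days: float = 12.0  # width of the mid-season spectral bump
    origin_xy: Tuple[float, float] = (1000.0, 2000.0)  # projected grid origin

    def __post_init__(self) -> None:
        if self.plant_spacing_m <= 0 or self.row_spacing_m <= 0:
            raise ValueError("spacings must be positive")
        if self.gsd_m <= 0:
            raise ValueError("gsd must be positive")
        tps = list(self.timepoints_dat)
        if tps != sorted(set(tps)) or not tps:
            raise ValueError("timepoints_dat must be non-empty, strictly increasing")
        if not 0.0 <= self.detector.miss_rate <= 1.0:
            raise ValueError("miss_rate must lie in [0, 1]")
        half_pitch = min(self.plant_spacing_m, self.row_spacing_m) / 2.0
        if self.growth.max_radius_m > half_pitch:
            raise ValueError(
                f"max_radius_m {self.growth.max_radius_m} exceeds half the "
                f"minimum spacing ({half_pitch}); plants would overlap"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "FieldConfig":
        d = dict(d)
        if "growth" in d and isinstance(d["growth"], Mapping):
            d["growth"] = GrowthParams(**d["growth"])
        if "weight_model" in d and isinstance(d["weight_model"], Mapping):
            d["weight_model"] = WeightModelParams(**d["weight_model"])
        if "detector" in d and isinstance(d["detector"], Mapping):
            d["detector"] = DetectorParams(**d["detector"])
        if "timepoints_dat" in d:
            d["timepoints_dat"] = tuple(int(t) for t in d["timepoints_dat"])
        if "origin_xy" in d:
            d["origin_xy"] = tuple(float(v) for v in d["origin_xy"])
        return cls(**d)


@dataclass
class SyntheticFieldBundle:
    """Everything a campaign produces, with ground truth attached.

    ``rasters[dat][layer]`` are float32 arrays sharing one geotransform;
    ``radii``/``plant_heights`` hold the rendered per-plant radius and apex
    height per time point (n_plants, n_tp); ``truth`` has one row per plant:
    plant_id, row, col, x, y, final_volume_cm3, midseason_ndvi, weight_g.
    """

    config: FieldConfig
    gt: GeoTransform
    shape: Tuple[int, int]
    rasters: Dict[int, Dict[str, np.ndarray]]
    grid: List[GridPoint]
    radii: Optional[np.ndarray]
    plant_heights: Optional[np.ndarray]
    truth: pd.DataFrame
    detections: Dict[int, List[BoundingBox]] = field(default_factory=dict)

    @property
    def tp_dat(self) -> List[int]:
        return sorted(self.rasters)

    def layers(self, dat: int, names: Sequence[str] = ALL_LAYERS) -> List[RasterLayer]:
        return [
            RasterLayer(values=self.rasters[dat][n], gt=self.gt, name=n)
            for n in names
        ]

    @property
    def n_plants(self) -> int:
        return len(self.grid)


def _logistic(t: np.ndarray, rate: float, midpoint: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-rate * (np.asarray(t, float) - midpoint)))


def _plant_trajectories(config: FieldConfig, vigor: np.ndarray):
    """Rendered radius and apex height per plant per time point."""
    g = config.growth
    t = np.asarray(config.timepoints_dat, dtype=float)
    s = _logistic(t, g.rate, g.midpoint_dat)  # (T,)
    cap = 0.95 * min(config.plant_spacing_m, config.row_spacing_m) / 2.0
    rmax = np.minimum(g.max_radius_m * np.sqrt(vigor), cap)  # (n,)
    hmax = g.max_height_m * vigor**2
    radii = g.seedling_radius_m + (rmax[:, None] - g.seedling_radius_m) * s[None, :]
    heights = g.seedling_height_m + (hmax[:, None] - g.seedling_height_m) * s[None, :]
    return radii, heights


def _field_geometry(config: FieldConfig):
    ox, oy = config.origin_xy
    xmax = ox + (config.n_cols - 1) * config.plant_spacing_m + config.margin_m
    xmin = ox - config.margin_m
    ymax = oy + (config.n_rows - 1) * config.row_spacing_m + config.margin_m
    ymin = oy - config.margin_m
    width = int(math.ceil((xmax - xmin) / config.gsd_m))
    height = int(math.ceil((ymax - ymin) / config.gsd_m))
    gt = GeoTransform(origin_x=xmin, origin_y=ymax,
                      gsd_x=config.gsd_m, gsd_y=config.gsd_m)
    return gt, (height, width)


def _plant_window(gt: GeoTransform, shape, x, y, r):
    """Pixel window (r0, r1, c0, c1) covering the disc of radius r at (x, y)."""
    c0 = max(0, int(math.floor((x - r - gt.origin_x) / gt.gsd_x)))
    c1 = min(shape[1], int(math.ceil((x + r - gt.origin_x) / gt.gsd_x)))
    r0 = max(0, int(math.floor((gt.origin_y - (y + r)) / gt.gsd_y)))
    r1 = min(shape[0], int(math.ceil((gt.origin_y - (y - r)) / gt.gsd_y)))
    return r0, r1, c0, c1


def _disc_geometry(gt: GeoTransform, shape, x, y, r):
    r0, r1, c0, c1 = _plant_window(gt, shape, x, y, r)
    xs = gt.origin_x + (np.arange(c0, c1) + 0.5) * gt.gsd_x
    ys = gt.origin_y - (np.arange(r0, r1) + 0.5) * gt.gsd_y
    dist = np.sqrt((xs[None, :] - x) ** 2 + (ys[:, None] - y) ** 2)
    return (r0, r1, c0, c1), dist


def generate_field(config: FieldConfig) -> SyntheticFieldBundle:
    """Render a full synthetic campaign from one seeded generator.

    Identical configs (including the seed) produce bit-identical bundles.
    """
    rng = np.random.default_rng(config.seed)
    gt, shape = _field_geometry(config)
    grid = build_grid(
        config.origin_xy,
        config.n_rows,
        config.n_cols,
        plant_spacing_m=config.plant_spacing_m,
        row_spacing_m=config.row_spacing_m,
    )
    n = len(grid)

    # plant-level randomness, drawn once in fixed order
    vigor = rng.lognormal(mean=0.0, sigma=config.growth.plant_sigma, size=n)
    chloro = rng.lognormal(mean=0.0, sigma=config.spectral_sigma, size=n)
    weight_noise = rng.normal(0.0, config.weight_model.noise_sd, size=n)

    radii, plant_heights = _plant_trajectories(config, vigor)
    tps = list(config.timepoints_dat)
    mid = config.growth.midpoint_dat
    bump = np.exp(
        -((np.asarray(tps, float) - mid) ** 2) / (2.0 * config.bump_width_days**2)
    )

    rasters: Dict[int, Dict[str, np.ndarray]] = {}
    for ti, dat in enumerate(tps):
        bands = {
            name: np.full(shape, SOIL_REFLECTANCE[name], dtype=np.float32)
            for name in RGB_LAYERS + MS_LAYERS
        }
        height = np.zeros(shape, dtype=np.float32)
        for pi, p in enumerate(grid):
            r = radii[pi, ti]
            (r0, r1, c0, c1), dist = _disc_geometry(gt, shape, p.x, p.y, r)
            inside = dist <= r
            for name in RGB_LAYERS + MS_LAYERS:
                val = VEG_REFLECTANCE[name]
                if name == "red":
                    val = val * (1.0 + (chloro[pi] - 1.0) * bump[ti])
                bands[name][r0:r1, c0:c1][inside] = val
            taper = np.cos(0.5 * np.pi * dist / r)
            h = (plant_heights[pi, ti] * taper).astype(np.float32)
            height[r0:r1, c0:c1][inside] = h[inside]
        if config.pixel_noise_sd > 0:
            for name in RGB_LAYERS + MS_LAYERS:
                noise = rng.normal(0.0, config.pixel_noise_sd, size=shape)
                bands[name] = np.clip(bands[name] + noise, 0.0, 1.0).astype(
                    np.float32
                )
        # quantize reflectance to the on-disk integer scale so the written
        # bundle round-trips losslessly
        for name in RGB_LAYERS + MS_LAYERS:
            bands[name] = (
                np.rint(bands[name] * REFLECTANCE_SCALE) / REFLECTANCE_SCALE
            ).astype(np.float32)
        bands["height"] = height
        rasters[dat] = bands

    # ground truth from the rendered rasters
    pixel_area_cm2 = config.gsd_m**2 * 1e4
    final_dat = tps[-1]
    mid_idx = min(range(len(tps)), key=lambda i: (abs(tps[i] - mid), tps[i]))
    mid_dat = tps[mid_idx]

    rows = []
    wm = config.weight_model
    for pi, p in enumerate(grid):
        (r0, r1, c0, c1), _ = _disc_geometry(
            gt, shape, p.x, p.y, radii[pi, -1]
        )
        h_fin = rasters[final_dat]["height"][r0:r1, c0:c1]
        support = h_fin > 0
        vol = canopy_volume(h_fin * 100.0, support, pixel_area_cm2)

        (m0, m1, mc0, mc1), _ = _disc_geometry(
            gt, shape, p.x, p.y, radii[pi, mid_idx]
        )
        h_mid = rasters[mid_dat]["height"][m0:m1, mc0:mc1]
        sup_mid = h_mid > 0
        nir = rasters[mid_dat]["NIR"][m0:m1, mc0:mc1][sup_mid]
        red = rasters[mid_dat]["red"][m0:m1, mc0:mc1][sup_mid]
        ndvi_mean = float(np.mean((nir - red) / (nir + red)))

        weight = wm.beta_volume * vol + wm.beta_spectral * ndvi_mean
        weight = max(weight + weight_noise[pi], 1.0)
        rows.append(
            {
                "plant_id": p.plant_id,
                "row": p.plant_id // config.n_cols,
                "col": p.plant_id % config.n_cols,
                "x": p.x,
                "y": p.y,
                "final_volume_cm3": vol,
                "midseason_ndvi": ndvi_mean,
                "weight_g": weight,
            }
        )
    truth = pd.DataFrame(rows)

    bundle = SyntheticFieldBundle(
        config=config,
        gt=gt,
        shape=shape,
        rasters=rasters,
        grid=grid,
        radii=radii,
        plant_heights=plant_heights,
        truth=truth,
    )
    for ti in range(len(tps)):
        bundle.detections[tps[ti]] = simulate_detections(bundle, ti)
    return bundle


def simulate_detections(
    bundle: SyntheticFieldBundle,
    tp: int,
    rng: Optional[np.random.Generator] = None,
    miss_rate: Optional[float] = None,
    jitter_sd_m: Optional[float] = None,
) -> List[BoundingBox]:
    """Emulated detector output for one time point (by index).

    One tight box per plant with a rendered radius > 0, each dropped
    independently with probability ``miss_rate`` and each edge jittered with
    N(0, jitter_sd_m). Deterministic for a fixed bundle seed and time point;
    pass ``rng`` to draw replicate detection sets.
    """
    tps = bundle.tp_dat
    if not 0 <= tp < len(tps):
        raise IndexError(f"time point index {tp} out of range")
    if bundle.radii is None:
        raise ValueError("bundle does not carry rendered radii")
    cfg = bundle.config
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 7001 + tp])
    if miss_rate is None:
        miss_rate = cfg.detector.miss_rate
    if jitter_sd_m is None:
        jitter_sd_m = cfg.detector.jitter_sd_m

    boxes: List[BoundingBox] = []
    for pi, p in enumerate(bundle.grid):
        r = float(bundle.radii[pi, tp])
        miss = rng.uniform() < miss_rate
        jit = rng.normal(0.0, jitter_sd_m, size=4) if jitter_sd_m > 0 else np.zeros(4)
        if r <= 0 or miss:
            continue
        xmin, xmax = p.x - r + jit[0], p.x + r + jit[1]
        ymin, ymax = p.y - r + jit[2], p.y + r + jit[3]
        if xmax - xmin < cfg.gsd_m:
            cx = (xmin + xmax) / 2
            xmin, xmax = cx - cfg.gsd_m / 2, cx + cfg.gsd_m / 2
        if ymax - ymin < cfg.gsd_m:
            cy = (ymin + ymax) / 2
            ymin, ymax = cy - cfg.gsd_m / 2, cy + cfg.gsd_m / 2
        boxes.append(BoundingBox(xmin, ymin, xmax, ymax, source_tp=tp))
    return boxes


def write_bundle(bundle: SyntheticFieldBundle, directory) -> dict:
    """Persist a bundle: GeoTIFF rasters, GeoJSON detections and grid, CSV
    truth table, YAML manifest. Returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    files: Dict[str, dict] = {}
    for dat in bundle.tp_dat:
        bands = bundle.rasters[dat]
        rgb_path = directory / f"rgb_dat{dat:03d}.tif"
        ms_path = directory / f"ms_dat{dat:03d}.tif"
        h_path = directory / f"height_dat{dat:03d}.tif"
        uio.write_geotiff(
            rgb_path,
            np.stack([bands[n] for n in RGB_LAYERS]),
            bundle.gt,
            RGB_LAYERS,
            scale=REFLECTANCE_SCALE,
        )
        uio.write_geotiff(
            ms_path,
            np.stack([bands[n] for n in MS_LAYERS]),
            bundle.gt,
            MS_LAYERS,
            scale=REFLECTANCE_SCALE,
        )
        uio.write_geotiff(h_path, bands["height"], bundle.gt, ["height"])
        files[str(dat)] = {
            "rgb": rgb_path.name,
            "ms": ms_path.name,
            "height": h_path.name,
        }

    uio.write_json(directory / "detections.geojson",
                   uio.boxes_to_geojson(bundle.detections))
    uio.write_json(directory / "grid.geojson", uio.grid_to_geojson(bundle.grid))
    bundle.truth.to_csv(directory / "truth.csv", index=False)

    manifest = {
        "config": bundle.config.to_dict(),
        "rasters": files,
        "detections": "detections.geojson",
        "grid": "grid.geojson",
        "truth": "truth.csv",
        "reflectance_scale": REFLECTANCE_SCALE,
    }
    uio.write_yaml(directory / "manifest.yaml", manifest)
    return manifest


def read_bundle(directory) -> SyntheticFieldBundle:
    """Reload a written bundle. Rendered per-plant radii are not persisted,
    so ``simulate_detections`` is unavailable on a reloaded bundle; the
    stored detections are."""
    directory = Path(directory)
    manifest = uio.read_yaml(directory / "manifest.yaml")
    config = FieldConfig.from_dict(manifest["config"])

    rasters: Dict[int, Dict[str, np.ndarray]] = {}
    gt = None
    shape = None
    for dat_str, entry in manifest["rasters"].items():
        dat = int(dat_str)
        bands: Dict[str, np.ndarray] = {}
        for key in ("rgb", "ms", "height"):
            arr, gt, names = uio.read_geotiff(directory / entry[key])
            for i, name in enumerate(names):
                bands[name] = arr[i].astype(np.float32)
        shape = bands["height"].shape
        rasters[dat] = bands

    detections = uio.geojson_to_boxes(uio.read_json(directory / manifest["detections"]))
    grid = uio.geojson_to_grid(uio.read_json(directory / manifest["grid"]))
    truth = pd.read_csv(directory / manifest["truth"])
    return SyntheticFieldBundle(
        config=config,
        gt=gt,
        shape=shape,
        rasters=rasters,
        grid=grid,
        radii=None,
        plant_heights=None,
        truth=truth,
        detections=detections,
    )
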