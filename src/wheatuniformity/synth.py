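"""Synthetic wheat-field generator.

Emulates the statistical structure of UAV-derived plot data so every
downstream stage (trait extraction, uniformity battery, yield association)
is testable without a field campaign: spatially correlated trait surfaces
over 1.5 x 1.25 m plots at 3 cm GSD with a 0.25 m row structure, bimodal
red/NIR reflectance scenes (soil vs. vegetation NDVI modes), plant-height
point clouds over a flat ground plane, and yield/biomass tables generated as
affine functions of a trait mean and a uniformity index plus noise.

Every generator is a pure function of ``(config, trait, plot_id, stage)``:
the RNG stream is keyed on those, so identical inputs give bit-identical
outputs regardless of call order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.stats import norm

from .raster import STAGES, TraitRaster

_TRAIT_CODES = {"LAI": 1, "SPAD": 2, "PH": 3, "NDVI": 4, "CLOUD": 5, "YIELD": 6}
_STAGE_CODES = {s: i + 1 for i, s in enumerate(STAGES)}


@dataclass
class FieldSimConfig:
    """All knobs of the synthetic field.

    Defaults reproduce the trial geometry the pipeline targets: 1.5 x 1.25 m
    plots, 0.25 m row spacing, 3 cm ground sampling distance.  Trait means
    and field-scale heterogeneity are realistic mid-season wheat values;
    ``heterogeneity`` maps each trait to ``(field_sd, correlation_length_m)``
    of its spatially correlated surface.  ``yield_coeffs``/``biomass_coeffs``
    are ``(a_mean, b_uniformity, noise_sd)`` in the generating model
    ``outcome = a_mean * trait_mean - b_uniformity * index + noise``.
    """

    n_plots: int = 12
    plot_width_m: float = 1.5
    plot_height_m: float = 1.25
    gsd_m: float = 0.03
    row_spacing_m: float = 0.25
    row_structure: bool = True
    trait_means: dict = field(
        default_factory=lambda: {"LAI": 3.2, "SPAD": 45.0, "PH": 80.0}
    )
    heterogeneity: dict = field(
        default_factory=lambda: {
            "LAI": (0.5, 0.15),
            "SPAD": (3.0, 0.15),
            "PH": (8.0, 0.15),
        }
    )
    soil_ndvi_mean: float = 0.12
    veg_ndvi_mean: float = 0.80
    noise_sd: float = 0.05
    yield_coeffs: tuple = (2.0, 5.0, 0.15)
    biomass_coeffs: tuple = (4.5, 9.0, 0.30)
    n_cloud_points: int = 4000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.gsd_m > 0:
            raise ValueError("gsd_m must be positive")
        if self.plot_width_m < 2 * self.gsd_m or self.plot_height_m < 2 * self.gsd_m:
            raise ValueError("plot dimensions must be at least 2 * gsd_m")
        if self.n_plots < 1:
            raise ValueError("n_plots must be a positive integer")
        for trait, (sd, clen) in self.heterogeneity.items():
            if sd < 0:
                raise ValueError(f"heterogeneity sd for {trait} must be >= 0")
            if not clen > 0:
                raise ValueError(f"correlation length for {trait} must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(rows, cols) of a plot raster at the configured GSD."""
        ny = max(2, int(round(self.plot_height_m / self.gsd_m)))
        nx = max(2, int(round(self.plot_width_m / self.gsd_m)))
        return ny, nx


@dataclass
class SpectralScene:
    """A simulated two-band reflectance scene with its ground truth."""

    red: TraitRaster
    nir: TraitRaster
    vegetation_mask: np.ndarray
    true_fvc: float


@dataclass
class PointCloud:
    """A simulated plant point cloud (x, y in m; z = height above ground, m)."""

    points: np.ndarray  # (n, 3)
    true_height_p97: float

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]


def _rng(cfg: FieldSimConfig, *codes: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed) & 0x7FFFFFFF, *codes])


def _check_plot(cfg: FieldSimConfig, plot_id: int) -> int:
    plot_id = int(plot_id)
    if not 0 <= plot_id < cfg.n_plots:
        raise ValueError(f"plot_id {plot_id} outside [0, {cfg.n_plots})")
    return plot_id


def row_mask(cfg: FieldSimConfig) -> np.ndarray:
    """Boolean vegetation mask of the row structure (True on crop rows).

    Rows run east-west, spaced ``row_spacing_m`` across the plot's north-south
    extent; each row is rendered as a vegetated stripe of width
    ``row_spacing_m / 2`` centred on the row centre, so by construction rows
    occupy half the plot area up to pixel quantization.
    """
    ny, nx = cfg.grid_shape
    if not cfg.row_structure:
        return np.ones((ny, nx), dtype=bool)
    y = (np.arange(ny) + 0.5) * cfg.gsd_m  # distance from north edge
    phase = np.mod(y, cfg.row_spacing_m)
    # half-open stripe [spacing/4, 3*spacing/4) centred on the row centre
    on_row = (phase >= cfg.row_spacing_m / 4) & (phase < 3 * cfg.row_spacing_m / 4)
    return np.repeat(on_row[:, None], nx, axis=1)


def _correlated_field(
    rng: np.random.Generator, shape: tuple[int, int], sd: float, clen_px: float
) -> np.ndarray:
    """Stationary Gaussian random field: smoothed white noise, rescaled to sd.

    White noise is convolved with a Gaussian kernel of bandwidth ``clen_px``
    (periodic boundary, so the field is stationary) and divided by the exact
    L2 norm of the discrete kernel so the marginal sd equals ``sd``.
    """
    white = rng.standard_normal(shape)
    if sd == 0:
        return np.zeros(shape)
    if clen_px <= 0.05:  # effectively uncorrelated
        return sd * white
    smoothed = gaussian_filter(white, sigma=clen_px, mode="wrap")
    impulse = np.zeros(8 * int(np.ceil(clen_px)) + 1)
    impulse[len(impulse) // 2] = 1.0
    k = gaussian_filter1d(impulse, sigma=clen_px, mode="constant")
    attenuation = np.sum(k**2)  # per-axis variance factor of the convolution
    return sd * smoothed / attenuation  # 2-D separable: sqrt(att^2) = att


def simulate_trait_raster(
    cfg: FieldSimConfig, trait: str, plot_id: int, stage: str | None = None
) -> TraitRaster:
    """Simulate one plot's trait surface (LAI, SPAD or PH).

    The surface is ``mean + correlated field + iid pixel noise``, clipped to
    be nonnegative; pixels between crop rows are flagged invalid when the row
    structure is enabled.
    """
    if trait not in cfg.trait_means:
        raise ValueError(
            f"unknown trait {trait!r}; valid tags: {sorted(cfg.trait_means)}"
        )
    plot_id = _check_plot(cfg, plot_id)
    stage_code = _STAGE_CODES.get(stage, 0)
    rng = _rng(cfg, 10, _TRAIT_CODES.get(trait, 99), plot_id, stage_code)

    sd, clen = cfg.heterogeneity.get(trait, (0.0, 0.1))
    vals = cfg.trait_means[trait] + _correlated_field(
        rng, cfg.grid_shape, sd, clen / cfg.gsd_m
    )
    if cfg.noise_sd > 0:
        vals = vals + rng.normal(0.0, cfg.noise_sd, cfg.grid_shape)
    vals = np.clip(vals, 0.0, None)
    return TraitRaster(
        values=vals,
        mask=row_mask(cfg),
        gsd_m=cfg.gsd_m,
        trait=trait,
        plot_id=f"plot_{plot_id:03d}",
        stage=stage,
    )


def simulate_spectral_scene(
    cfg: FieldSimConfig, plot_id: int, stage: str | None = None
) -> SpectralScene:
    """Simulate a red/NIR scene whose NDVI histogram is bimodal.

    Vegetation pixels (crop rows) and soil pixels (inter-row) receive NDVI
    values around ``veg_ndvi_mean`` and ``soil_ndvi_mean`` respectively, plus
    iid noise; reflectances are back-computed at a constant total reflectance
    so the per-pixel NDVI is exact.  The true vegetation mask and the true
    FVC (its pixel fraction, exactly) are recorded.
    """
    plot_id = _check_plot(cfg, plot_id)
    if cfg.veg_ndvi_mean - cfg.soil_ndvi_mean <= 4 * cfg.noise_sd:
        warnings.warn(
            "NDVI modes closer than 4x pixel noise sd; valley detection is "
            "not guaranteed",
            stacklevel=2,
        )
    stage_code = _STAGE_CODES.get(stage, 0)
    rng = _rng(cfg, 20, _TRAIT_CODES["NDVI"], plot_id, stage_code)

    veg = row_mask(cfg)
    ndvi = np.where(veg, cfg.veg_ndvi_mean, cfg.soil_ndvi_mean)
    ndvi = ndvi + rng.normal(0.0, cfg.noise_sd, cfg.grid_shape)
    ndvi = np.clip(ndvi, -0.95, 0.95)

    total = 0.6  # red + NIR reflectance, constant across the scene
    nir = total * (1.0 + ndvi) / 2.0
    red = total - nir
    common = dict(
        mask=np.ones(cfg.grid_shape, bool),
        gsd_m=cfg.gsd_m,
        plot_id=f"plot_{plot_id:03d}",
        stage=stage,
    )
    return SpectralScene(
        red=TraitRaster(values=red, trait="red", **common),
        nir=TraitRaster(values=nir, trait="nir", **common),
        vegetation_mask=veg,
        true_fvc=float(veg.mean()),
    )


def simulate_point_cloud(cfg: FieldSimConfig, plot_id: int) -> PointCloud:
    """Simulate a plant point cloud above a zero ground plane.

    Heights are drawn Normal(mean, sd) with the configured PH mean/sd
    (converted cm -> m); the 97th percentile of that generating distribution
    is recorded as ground truth.
    """
    plot_id = _check_plot(cfg, plot_id)
    rng = _rng(cfg, 30, _TRAIT_CODES["CLOUD"], plot_id)
    mean_m = cfg.trait_means["PH"] / 100.0
    sd_m = cfg.heterogeneity.get("PH", (8.0, 0.15))[0] / 100.0
    x = rng.uniform(0.0, cfg.plot_width_m, cfg.n_cloud_points)
    y = rng.uniform(0.0, cfg.plot_height_m, cfg.n_cloud_points)
    z = rng.normal(mean_m, sd_m, cfg.n_cloud_points) if sd_m > 0 else np.full(
        cfg.n_cloud_points, mean_m
    )
    truth = float(norm.ppf(0.97, loc=mean_m, scale=sd_m)) if sd_m > 0 else mean_m
    return PointCloud(points=np.column_stack([x, y, z]), true_height_p97=truth)


def simulate_yield_table(
    cfg: FieldSimConfig,
    uniformity_values: np.ndarray,
    trait_means: np.ndarray,
    plot_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Generate per-plot yield and biomass (Mg/ha) from mean and uniformity.

    ``outcome = a_mean * trait_mean - b_uniformity * index + Normal(0, sd)``
    with ``cfg.yield_coeffs`` and ``cfg.biomass_coeffs``.  Higher values of
    the uniformity index (less even growth) reduce the outcome, encoding the
    negative index-outcome association the pipeline is meant to recover.
    The generating coefficients are stored in ``DataFrame.attrs``.
    """
    u = np.asarray(uniformity_values, dtype=float)
    m = np.asarray(trait_means, dtype=float)
    if u.shape != m.shape or u.ndim != 1:
        raise ValueError("uniformity_values and trait_means must be equal-length 1-D")
    n = len(u)
    rng = _rng(cfg, 40, _TRAIT_CODES["YIELD"], n)
    ay, by, sy = cfg.yield_coeffs
    ab, bb, sb = cfg.biomass_coeffs
    yld = ay * m - by * u + (rng.normal(0.0, sy, n) if sy > 0 else 0.0)
    bio = ab * m - bb * u + (rng.normal(0.0, sb, n) if sb > 0 else 0.0)
    if plot_ids is None:
        plot_ids = [f"plot_{i:03d}" for i in range(n)]
    df = pd.DataFrame(
        {"plot_id": plot_ids, "yield_mg_ha": yld, "biomass_mg_ha": bio}
    )
    df.attrs["yield_coeffs"] = tuple(cfg.yield_coeffs)
    df.attrs["biomass_coeffs"] = tuple(cfg.biomass_coeffs)
    return df
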