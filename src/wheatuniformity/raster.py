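"""Plot-level trait rasters.

A :class:`TraitRaster` is a single-band grid of one agronomic trait over one
field plot, together with a boolean validity mask, a ground sampling distance
(GSD, metres per pixel) and identification tags (trait, plot, growth stage).

Conventions
-----------
* raster row 0 is the north edge of the plot;
* pixels are registered at their centres: the centre of pixel ``(i, j)`` lies
  ``(j + 0.5) * gsd_m`` metres east of the plot's NW corner and
  ``(i + 0.5) * gsd_m`` metres south of it;
* ``mask`` uses ``True`` (1) for valid / vegetation pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: The seven wheat growth stages used throughout: tillering, jointing,
#: heading, flowering, early/middle/late grain filling.
STAGES: tuple[str, ...] = ("TS", "JS", "HS", "FS", "EFS", "MFS", "LFS")

#: The four agronomic traits the uniformity battery covers.
TRAITS: tuple[str, ...] = ("FVC", "LAI", "SPAD", "PH")


@dataclass
class TraitRaster:
    """One trait's values on a regular grid over a plot.

    Parameters
    ----------
    values
        2-D float array of trait values (LAI and SPAD dimensionless, PH in
        cm, reflectance / NDVI dimensionless).
    mask
        2-D boolean array, same shape as ``values``; ``True`` marks valid
        pixels.  Values under ``False`` entries are ignored everywhere.
    gsd_m
        Ground sampling distance in metres per pixel; must be positive.
    trait
        Trait tag, e.g. ``"LAI"``, ``"NDVI"``, ``"red"``.
    plot_id, stage
        Optional identification tags carried through the pipeline.
    """

    values: np.ndarray
    mask: np.ndarray
    gsd_m: float
    trait: str
    plot_id: str = ""
    stage: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        if self.mask.shape != self.values.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != values shape {self.values.shape}"
            )
        if not self.gsd_m > 0:
            raise ValueError(f"gsd_m must be positive, got {self.gsd_m}")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite values under valid mask")

    # -- basic accessors -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_values(self) -> np.ndarray:
        """1-D array of values at valid pixels."""
        return self.values[self.mask]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-centre coordinates (x east, y north) in the local plot frame.

        Origin is the plot's SW corner, x grows east, y grows north; row 0
        (north edge) therefore has the largest y.  Returns two 2-D arrays.
        """
        ny, nx = self.shape
        x = (np.arange(nx) + 0.5) * self.gsd_m
        y = (ny - np.arange(ny) - 0.5) * self.gsd_m
        return np.meshgrid(x, y)

    def with_mask(self, mask: np.ndarray) -> "TraitRaster":
        """Copy of this raster with ``mask`` replaced (ANDed with nothing)."""
        return replace(self, values=self.values.copy(), mask=np.asarray(mask, bool))


def roi_mask(raster: TraitRaster, roi) -> np.ndarray:
    """Boolean mask of pixels whose centre lies inside a shapely polygon.

    A pixel belongs to the plot iff its centre is inside (or on the boundary
    of) ``roi``, in the raster's local metric frame.  ``roi=None`` selects
    every pixel.
    """
    if roi is None:
        return np.ones(raster.shape, dtype=bool)
    import shapely

    xs, ys = raster.pixel_centers()
    inside = shapely.contains_xy(roi, xs.ravel(), ys.ravel())
    boundary = shapely.intersects(shapely.points(xs.ravel(), ys.ravel()), roi.boundary)
    return (inside | boundary).reshape(raster.shape)
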