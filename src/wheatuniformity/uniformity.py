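"""Entropy- and variance-based canopy uniformity indices.

The central idea: a plot's per-pixel trait map (LAI, SPAD, plant height) is
discretised into classes with a *classification parameter* — a bin width in
trait units — turning the pixel population into an abundance distribution
(S nonempty classes with proportions P_i), on which the ecological evenness
battery is evaluated:

====================  =============================================
Shannon entropy       H' = -sum P_i ln P_i
Pielou's index        J' = H' / ln S
Alatalo's index       E  = (1/sum P_i^2 - 1) / (exp H' - 1)
Sheldon's index       E_s = exp(H') / S
Heip's index          E_h = (exp(H') - 1) / (S - 1)
====================  =============================================

together with the dispersion statistics mean, sample variance, coefficient
of variation (std/mean), and optionally Lloyd's mean crowding
m* = x + s^2/x - 1 and the clustering index I = s^2/x - 1.

FVC needs no binning: each pixel is already 0 (background) or 1
(vegetation), a two-class distribution (1 - FVC, FVC).

Conventions (stated because they fix otherwise ambiguous values):

* natural logarithm throughout;
* sample variance with n - 1 denominator;
* bins are half-open [edge, edge + width) anchored at a configurable origin
  (default 0 in trait units); empty bins are dropped, so the abundance S
  counts nonempty classes only;
* when S = 1 (all pixels in one class — perfectly uniform growth) Pielou and
  Alatalo are the indeterminate form 0/0 and are defined as 0, placing
  perfect uniformity at the low end of the index;
* statistics that are undefined (e.g. CV at mean 0) are reported as NaN,
  never dropped silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import TraitRaster, roi_mask

#: Default classification parameters (bin widths) per trait; PH is in cm.
DEFAULT_BIN_WIDTHS = {"LAI": 0.5, "SPAD": 2.0, "PH": 2.0}

#: The six battery statistics emitted per trait.
INDEX_NAMES = ("mean", "variance", "cv", "shannon", "pielou", "alatalo")

_TRAIT_LETTER = {"FVC": "F", "LAI": "L", "SPAD": "S", "PH": "P"}
_INDEX_CODE = {"mean": "M", "variance": "V", "cv": "CV",
               "shannon": "H", "pielou": "J", "alatalo": "E"}


def index_abbreviation(trait: str, index: str) -> str:
    """Canonical short code of a (trait, index) pair: FM, FV, ..., PHH, ..., PE.

    Plant-height Shannon entropy is "PHH" (avoiding a clash with the PH trait
    tag); all other codes are trait letter + index code.
    """
    if trait == "PH" and index == "shannon":
        return "PHH"
    return _TRAIT_LETTER[trait] + _INDEX_CODE[index]


@dataclass
class ClassDistribution:
    """A binned trait distribution: the input to the evenness indices.

    ``bin_indices`` are the integer class labels ``floor((v - origin)/width)``
    of the nonempty bins, ``counts`` the pixel counts per nonempty bin.
    """

    bin_width: float
    origin: float
    bin_indices: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_indices = np.asarray(self.bin_indices)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if not self.bin_width > 0:
            raise ValueError(f"bin_width must be positive, got {self.bin_width}")
        if len(self.counts) == 0:
            raise ValueError("distribution has no classes")
        if np.any(self.counts <= 0):
            raise ValueError("all stored class counts must be positive")
        if len(self.bin_indices) != len(self.counts):
            raise ValueError("bin_indices and counts disagree in length")

    @property
    def S(self) -> int:
        """Abundance: the number of nonempty classes."""
        return len(self.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        """P_i = count_i / total; sums to 1."""
        return self.counts / self.counts.sum()


def bin_values(
    values: np.ndarray, bin_width: float, origin: float = 0.0
) -> ClassDistribution:
    """Discretise trait values into half-open classes [edge, edge + width).

    Value v belongs to class ``floor((v - origin) / bin_width)``; empty
    classes are dropped.
    """
    if not bin_width > 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("need at least one value")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values cannot be binned")
    idx = np.floor((v - origin) / bin_width).astype(np.int64)
    uniq, counts = np.unique(idx, return_counts=True)
    return ClassDistribution(
        bin_width=float(bin_width), origin=float(origin),
        bin_indices=uniq, counts=counts,
    )


# ---------------------------------------------------------------------------
# Entropy / evenness indices
# ---------------------------------------------------------------------------

def shannon_entropy(dist: ClassDistribution) -> float:
    """H' = -sum P_i ln P_i, in nats; 0 <= H' <= ln S."""
    p = dist.proportions
    return float(-np.sum(p * np.log(p)))


def pielou_index(dist: ClassDistribution) -> float:
    """J' = H' / ln S in [0, 1]; defined as 0 when S = 1."""
    if dist.S == 1:
        return 0.0
    return shannon_entropy(dist) / math.log(dist.S)


def alatalo_index(dist: ClassDistribution) -> float:
    """E = (1/sum P_i^2 - 1) / (exp H' - 1) in [0, 1]; 0 when S = 1."""
    if dist.S == 1:
        return 0.0
    p = dist.proportions
    num = 1.0 / float(np.sum(p**2)) - 1.0
    den = math.exp(shannon_entropy(dist)) - 1.0
    return num / den


def sheldon_index(dist: ClassDistribution) -> float:
    """E_s = exp(H') / S in (0, 1]; equals 1 at perfect evenness."""
    return math.exp(shannon_entropy(dist)) / dist.S


def heip_index(dist: ClassDistribution) -> float:
    """E_h = (exp(H') - 1) / (S - 1); requires S >= 2."""
    if dist.S < 2:
        raise ValueError("Heip's index requires at least two classes")
    return (math.exp(shannon_entropy(dist)) - 1.0) / (dist.S - 1)


# ---------------------------------------------------------------------------
# Dispersion statistics
# ---------------------------------------------------------------------------

@dataclass
class DispersionStats:
    mean: float
    variance: float
    cv: float
    mean_crowding: float
    clustering: float


def dispersion_stats(values: np.ndarray) -> DispersionStats:
    """Mean, sample variance (n-1), CV = std/mean, Lloyd's m*, clustering I.

    Ratios with a zero mean are reported as NaN.  A single value has zero
    spread by convention (variance 0).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("need at least one value")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values")
    mean = float(v.mean())
    var = float(v.var(ddof=1)) if v.size > 1 else 0.0
    if mean == 0.0:
        cv = mc = ci = float("nan")
    else:
        cv = math.sqrt(var) / mean
        ci = var / mean - 1.0
        mc = mean + ci
    return DispersionStats(mean=mean, variance=var, cv=cv,
                           mean_crowding=mc, clustering=ci)


# ---------------------------------------------------------------------------
# Plot-level batteries
# ---------------------------------------------------------------------------

@dataclass
class UniformityRecord:
    """One long-format result row: (plot, stage, trait, index, value)."""

    plot_id: str
    stage: str | None
    trait: str
    index: str
    value: float

    @property
    def abbreviation(self) -> str:
        return index_abbreviation(self.trait, self.index)


def fvc_distribution(vegetation_mask: TraitRaster | np.ndarray, roi=None) -> ClassDistribution:
    """Two-class distribution of the 0/1 vegetation indicator over the ROI.

    P = (1 - FVC, FVC); if every ROI pixel falls in one class then S = 1.
    """
    if isinstance(vegetation_mask, TraitRaster):
        sel = vegetation_mask.mask & roi_mask(vegetation_mask, roi)
        indicator = vegetation_mask.values[sel] > 0.5
    else:
        indicator = np.asarray(vegetation_mask).astype(bool).ravel()
    if indicator.size == 0:
        raise ValueError("empty ROI: no pixels to classify")
    n1 = int(indicator.sum())
    n0 = indicator.size - n1
    idx = [i for i, n in ((0, n0), (1, n1)) if n > 0]
    cnt = [n for n in (n0, n1) if n > 0]
    return ClassDistribution(bin_width=1.0, origin=0.0,
                             bin_indices=np.array(idx), counts=np.array(cnt))


def _records_from_values(
    values: np.ndarray, dist: ClassDistribution, plot_id: str,
    stage: str | None, trait: str,
) -> list[UniformityRecord]:
    d = dispersion_stats(values)
    stats = {
        "mean": d.mean,
        "variance": d.variance,
        "cv": d.cv,
        "shannon": shannon_entropy(dist),
        "pielou": pielou_index(dist),
        "alatalo": alatalo_index(dist),
    }
    return [UniformityRecord(plot_id, stage, trait, k, float(v))
            for k, v in stats.items()]


def uniformity_battery(
    raster: TraitRaster,
    roi=None,
    bin_width: float | None = None,
    crop_mask: TraitRaster | np.ndarray | None = None,
    origin: float = 0.0,
) -> list[UniformityRecord]:
    """The six battery statistics for one continuous-trait raster.

    Valid pixels are the raster's own mask intersected with the ROI and,
    when supplied, with the binary crop mask (so uniformity is computed over
    vegetation only).  ``bin_width`` defaults per trait to the standard
    classification parameters (LAI 0.5, SPAD 2, PH 2 cm).
    """
    if bin_width is None:
        bin_width = DEFAULT_BIN_WIDTHS.get(raster.trait)
        if bin_width is None:
            raise ValueError(
                f"no default bin width for trait {raster.trait!r}; pass bin_width"
            )
    sel = raster.mask & roi_mask(raster, roi)
    if crop_mask is not None:
        cm = crop_mask.values > 0.5 if isinstance(crop_mask, TraitRaster) else np.asarray(crop_mask, bool)
        sel &= cm
    values = raster.values[sel]
    if values.size == 0:
        raise ValueError(
            f"no valid pixels for plot {raster.plot_id!r} stage {raster.stage!r}"
        )
    dist = bin_values(values, bin_width, origin)
    return _records_from_values(values, dist, raster.plot_id, raster.stage, raster.trait)


def fvc_battery(vegetation_mask: TraitRaster, roi=None) -> list[UniformityRecord]:
    """The six battery statistics for the binary FVC indicator.

    FVC always uses every ROI pixel (vegetation and background alike): the
    indicator itself is the trait.
    """
    sel = vegetation_mask.mask & roi_mask(vegetation_mask, roi)
    indicator = (vegetation_mask.values[sel] > 0.5).astype(float)
    if indicator.size == 0:
        raise ValueError(
            f"no ROI pixels for plot {vegetation_mask.plot_id!r} "
            f"stage {vegetation_mask.stage!r}"
        )
    dist = fvc_distribution(indicator.astype(bool))
    return _records_from_values(indicator, dist,
                                vegetation_mask.plot_id, vegetation_mask.stage, "FVC")


def full_battery(
    trait_rasters: dict[str, TraitRaster],
    vegetation_mask: TraitRaster,
    roi=None,
    bin_widths: dict[str, float] | None = None,
    use_crop_mask: bool = True,
) -> list[UniformityRecord]:
    """The full 24-statistic battery for one plot-stage.

    Six statistics (mean, variance, CV, Shannon, Pielou, Alatalo) for each of
    FVC, LAI, SPAD and PH: 20 uniformity indices plus the 4 trait means.
    LAI/SPAD/PH are computed over vegetation pixels when ``use_crop_mask``.
    """
    widths = dict(DEFAULT_BIN_WIDTHS)
    if bin_widths:
        widths.update(bin_widths)
    records = fvc_battery(vegetation_mask, roi)
    for trait in ("LAI", "SPAD", "PH"):
        if trait not in trait_rasters:
            continue
        records.extend(
            uniformity_battery(
                trait_rasters[trait], roi=roi, bin_width=widths[trait],
                crop_mask=vegetation_mask if use_crop_mask else None,
            )
        )
    return records


def records_to_frame(records: list[UniformityRecord]) -> pd.DataFrame:
    """Long-format DataFrame (plot_id, stage, trait, index, abbreviation, value)."""
    return pd.DataFrame(
        {
            "plot_id": [r.plot_id for r in records],
            "stage": [r.stage for r in records],
            "trait": [r.trait for r in records],
            "index": [r.index for r in records],
            "abbreviation": [r.abbreviation for r in records],
            "value": [r.value for r in records],
        }
    )
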