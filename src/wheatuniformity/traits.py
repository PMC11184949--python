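"""Per-plot agronomic trait extraction.

Four traits feed the uniformity battery:

* **FVC** — fractional vegetation cover, obtained by thresholding an NDVI
  raster at the valley of its bimodal (soil vs. vegetation) histogram;
* **PH** — plant height, the 97th percentile of ground-normalised point
  cloud elevations;
* **LAI** and **SPAD** — predicted per pixel by a small single-hidden-layer
  feed-forward network regressed on spectral features.

NDVI is computed from the red (669 nm) and NIR (820 nm) bands as
``(NIR - red) / (NIR + red)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

from .raster import TraitRaster, roi_mask


# ---------------------------------------------------------------------------
# NDVI and vegetation segmentation
# ---------------------------------------------------------------------------

def compute_ndvi(red: TraitRaster, nir: TraitRaster) -> TraitRaster:
    """Per-pixel NDVI = (NIR - red) / (NIR + red).

    Masks are intersected; pixels where ``NIR + red == 0`` are additionally
    marked invalid.  For nonnegative reflectances the result lies in [-1, 1].
    """
    if red.shape != nir.shape:
        raise ValueError(f"shape mismatch: red {red.shape} vs nir {nir.shape}")
    denom = nir.values + red.values
    valid = red.mask & nir.mask & (denom != 0)
    out = np.zeros_like(denom)
    np.divide(nir.values - red.values, denom, out=out, where=valid)
    return TraitRaster(
        values=out,
        mask=valid,
        gsd_m=red.gsd_m,
        trait="NDVI",
        plot_id=red.plot_id,
        stage=red.stage,
    )


@dataclass
class ThresholdResult:
    """Valley-based NDVI segmentation threshold.

    ``threshold`` is the arithmetic mean of the per-stage valley NDVI values.
    """

    per_stage_valleys: list[float]
    threshold: float

    def __post_init__(self) -> None:
        if not -1 < self.threshold < 1:
            raise ValueError(f"threshold {self.threshold} outside (-1, 1)")


def _histogram_valley(
    values: np.ndarray, hist_bin: float, smooth_window: int, label: str
) -> float:
    """Valley between the two highest modes of a smoothed NDVI histogram."""
    edges = np.arange(-1.0, 1.0 + hist_bin / 2, hist_bin)
    counts, _ = np.histogram(values, bins=edges)
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(counts.astype(float), kernel, mode="same")
    peaks, _props = find_peaks(smoothed)
    if len(peaks) < 2:
        raise ValueError(
            f"NDVI histogram for {label} is unimodal after smoothing; "
            "supply a manual threshold"
        )
    top2 = sorted(sorted(peaks, key=lambda m: -smoothed[m])[:2])
    lo, hi = int(top2[0]), int(top2[1])
    if hi - lo < 2:
        raise ValueError(
            f"NDVI histogram for {label} has no interior bin between its two "
            "modes; supply a manual threshold"
        )
    between = np.arange(lo + 1, hi)
    minval = smoothed[between].min()
    ties = between[smoothed[between] == minval]
    valley_bin = int(np.median(ties))  # centre of a flat (e.g. zero-count) valley
    centers = (edges[:-1] + edges[1:]) / 2
    return float(centers[valley_bin])


def find_valley_threshold(
    ndvi_per_stage: Sequence[TraitRaster | np.ndarray],
    hist_bin: float = 0.02,
    smooth_window: int = 5,
    stage_labels: Sequence[str] | None = None,
) -> ThresholdResult:
    """Average valley threshold over growth stages.

    For each stage, the valid NDVI values are histogrammed on [-1, 1] with
    bin width ``hist_bin``, smoothed with a centred ``smooth_window``-bin
    moving average, and the minimum-count bin centre strictly between the two
    highest local maxima is taken as that stage's valley.  The segmentation
    threshold is the mean of the per-stage valleys.
    """
    if len(ndvi_per_stage) == 0:
        raise ValueError("at least one stage of NDVI values is required")
    valleys = []
    for i, item in enumerate(ndvi_per_stage):
        if isinstance(item, TraitRaster):
            vals, label = item.valid_values(), item.stage or f"stage {i}"
        else:
            vals = np.asarray(item, float).ravel()
            label = f"stage {i}"
        if stage_labels is not None:
            label = stage_labels[i]
        valleys.append(_histogram_valley(vals, hist_bin, smooth_window, label))
    return ThresholdResult(per_stage_valleys=valleys, threshold=float(np.mean(valleys)))


def compute_fvc(
    ndvi: TraitRaster, threshold: float, roi=None
) -> tuple[float, TraitRaster]:
    """Fractional vegetation cover of the plot and the binary crop mask.

    FVC is the number of ROI pixels whose NDVI strictly exceeds ``threshold``
    divided by the number of ROI pixels; ties to the threshold count as
    background.  The returned raster holds the 0/1 vegetation indicator,
    valid over the ROI.
    """
    if not -1 < threshold < 1:
        raise ValueError(f"threshold {threshold} outside (-1, 1)")
    in_roi = roi_mask(ndvi, roi)
    n_total = int(in_roi.sum())
    if n_total == 0:
        raise ValueError("empty ROI: no pixel centre falls inside the polygon")
    veg = in_roi & ndvi.mask & (ndvi.values > threshold)
    fvc = veg.sum() / n_total
    crop_mask = TraitRaster(
        values=veg.astype(float),
        mask=in_roi,
        gsd_m=ndvi.gsd_m,
        trait="FVC",
        plot_id=ndvi.plot_id,
        stage=ndvi.stage,
    )
    return float(fvc), crop_mask


# ---------------------------------------------------------------------------
# Plant height
# ---------------------------------------------------------------------------

def estimate_plant_height(points: np.ndarray, percentile: float = 97.0) -> float:
    """Plot-level plant height: a percentile of point elevations.

    ``points`` may be an (n, 3) x/y/z array or a 1-D array of z values,
    already ground-normalised (z = height above ground).  Uses the
    linear-interpolation order-statistic convention, so e.g. the 97th
    percentile of z = 0.00, 0.01, ..., 1.00 is exactly 0.97.
    """
    pts = np.asarray(points, dtype=float)
    z = pts[:, 2] if pts.ndim == 2 else pts
    if z.size == 0:
        raise ValueError("empty point cloud")
    return float(np.percentile(z, percentile, method="linear"))


# ---------------------------------------------------------------------------
# LAI / SPAD feature regression
# ---------------------------------------------------------------------------

@dataclass
class RegressorConfig:
    """Hyperparameters of the feature->trait network.

    One hidden layer of ``hidden_units`` tanh neurons (10 for LAI, 20 for
    SPAD), linear output, plain stochastic gradient backpropagation for
    ``iterations`` steps at ``learning_rate``, after a seeded split with
    ``train_fraction`` of samples for training (2:1 train:test).
    """

    hidden_units: int = 10
    iterations: int = 5000
    learning_rate: float = 0.005
    train_fraction: float = 2 / 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units <= 0 or self.iterations <= 0 or self.learning_rate <= 0:
            raise ValueError("hidden_units, iterations, learning_rate must be positive")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class FitReport:
    r2_train: float
    rmse_train: float
    r2_test: float
    rmse_test: float
    degenerate_target: bool = False


class TraitRegressor:
    """Single-hidden-layer feed-forward trait regressor.

    Inputs and targets are standardised before training and predictions are
    de-standardised, so the learning rate is scale-free.  Fixed seed gives an
    identical fit.
    """

    def __init__(self, cfg: RegressorConfig):
        self.cfg = cfg
        self._xscaler = StandardScaler()
        self._yscaler = StandardScaler()
        self._net = MLPRegressor(
            hidden_layer_sizes=(cfg.hidden_units,),
            activation="tanh",
            solver="sgd",
            learning_rate="constant",
            learning_rate_init=cfg.learning_rate,
            max_iter=cfg.iterations,
            n_iter_no_change=cfg.iterations,  # run the full iteration budget
            tol=0.0,
            random_state=cfg.seed,
        )
        self.report: FitReport | None = None

    def fit(self, features: np.ndarray, targets: np.ndarray) -> "TraitRegressor":
        X = np.asarray(features, dtype=float)
        y = np.asarray(targets, dtype=float).ravel()
        if X.ndim == 1:
            X = X[:, None]
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite features or targets")
        if len(X) < 3:
            raise ValueError(f"need at least 3 samples, got {len(X)}")
        if len(X) != len(y):
            raise ValueError("features and targets disagree in length")
        degenerate = bool(np.ptp(y) == 0)
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=self.cfg.train_fraction, random_state=self.cfg.seed
        )
        Xs = self._xscaler.fit_transform(X_tr)
        if degenerate:
            # constant target: the mean predictor is exact, no training needed
            self._const = float(y_tr[0])
            self.report = FitReport(
                r2_train=float("nan"),
                rmse_train=0.0,
                r2_test=float("nan"),
                rmse_test=float(np.sqrt(mean_squared_error(y_te, np.full_like(y_te, self._const)))),
                degenerate_target=True,
            )
            return self
        self._const = None
        ys = self._yscaler.fit_transform(y_tr[:, None]).ravel()
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")  # ConvergenceWarning at the fixed budget
            self._net.fit(Xs, ys)
        self.report = FitReport(
            r2_train=float(r2_score(y_tr, self.predict(X_tr))),
            rmse_train=float(np.sqrt(mean_squared_error(y_tr, self.predict(X_tr)))),
            r2_test=float(r2_score(y_te, self.predict(X_te))),
            rmse_test=float(np.sqrt(mean_squared_error(y_te, self.predict(X_te)))),
        )
        return self

    def predict(self, features: np.ndarray) -> np.ndarray:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self._const is not None:
            return np.full(len(X), self._const)
        ys = self._net.predict(self._xscaler.transform(X))
        return self._yscaler.inverse_transform(ys[:, None]).ravel()


def train_trait_regressor(
    features: np.ndarray, targets: np.ndarray, cfg: RegressorConfig | None = None
) -> tuple[TraitRegressor, FitReport]:
    """Fit the feature->trait network; returns the regressor and its report.

    The report carries R^2 and RMSE on the seeded train and test splits.  A
    constant target is flagged degenerate (R^2 undefined, RMSE 0 attainable).
    """
    cfg = cfg or RegressorConfig()
    reg = TraitRegressor(cfg).fit(features, targets)
    assert reg.report is not None
    return reg, reg.report


def predict_trait_raster(
    regressor, feature_rasters: Sequence[TraitRaster], trait: str = "LAI"
) -> TraitRaster:
    """Per-pixel trait prediction from a stack of feature rasters.

    ``regressor`` is anything with a ``predict`` method over (n, p) arrays.
    The output mask is the intersection of the feature masks; masked pixels
    stay masked and carry value 0.
    """
    if len(feature_rasters) == 0:
        raise ValueError("need at least one feature raster")
    shape = feature_rasters[0].shape
    mask = np.ones(shape, bool)
    for r in feature_rasters:
        if r.shape != shape:
            raise ValueError("feature rasters disagree in shape")
        mask &= r.mask
    X = np.column_stack([r.values[mask] for r in feature_rasters])
    out = np.zeros(shape)
    if mask.any():
        out[mask] = np.asarray(regressor.predict(X), dtype=float).ravel()
    ref = feature_rasters[0]
    return TraitRaster(
        values=out, mask=mask, gsd_m=ref.gsd_m, trait=trait,
        plot_id=ref.plot_id, stage=ref.stage,
    )
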