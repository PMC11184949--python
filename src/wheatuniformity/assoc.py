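"""Uniformity-to-outcome association.

Relates the per-plot uniformity indices to grain yield and final biomass
(Mg/ha): stage-wise Pearson correlations, multiple linear regression fitted
on a seeded 7:3 train/validation split, evaluation of the four frozen
published regression models (yield/biomass from trait means or from
uniformity indices), cultivar clustering with ANOVA, and the two sensitivity
analyses — classification-parameter (bin width) sweeps and spatial
resolution (GSD) degradation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.model_selection import train_test_split

from .raster import TraitRaster
from .uniformity import alatalo_index, bin_values, pielou_index, shannon_entropy

FROZEN_MODEL_NAMES = ("yield_mean", "biomass_mean", "yield_index", "biomass_index")


# ---------------------------------------------------------------------------
# Linear models (fitted and frozen)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearModel:
    """A named linear predictor: response = intercept + sum(coef * value)."""

    predictor_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    response: str
    provenance: str = "fitted"

    def __post_init__(self) -> None:
        if len(self.predictor_names) != len(self.coefficients):
            raise ValueError("one coefficient per predictor is required")


def load_frozen_model(name: str) -> LinearModel:
    """Load one of the four shipped published regression models.

    ``name`` is one of ``yield_mean``, ``biomass_mean`` (predictors are the
    FVC/LAI/SPAD/PH plot means at the jointing, flowering and late-filling
    stages) or ``yield_index``, ``biomass_index`` (predictors are the FE, LJ,
    SJ uniformity indices plus the PM mean at the same stages).
    """
    if name not in FROZEN_MODEL_NAMES:
        raise ValueError(f"unknown frozen model {name!r}; choose from {FROZEN_MODEL_NAMES}")
    raw = json.loads(
        resources.files("wheatuniformity.data").joinpath("frozen_models.json").read_text()
    )[name]
    return LinearModel(
        predictor_names=tuple(raw["predictors"].keys()),
        coefficients=tuple(raw["predictors"].values()),
        intercept=float(raw["intercept"]),
        response=raw["response"],
        provenance=raw["provenance"],
    )


def evaluate_model(model: LinearModel, predictors: Mapping[str, float]) -> float:
    """Evaluate ``model`` at named predictor values (exact arithmetic contract)."""
    missing = [p for p in model.predictor_names if p not in predictors]
    if missing:
        raise KeyError(f"missing predictors: {missing}")
    return float(
        model.intercept
        + sum(c * float(predictors[p])
              for p, c in zip(model.predictor_names, model.coefficients))
    )


@dataclass
class MLRReport:
    r2_train: float
    rmse_train: float
    r2_validation: float
    rmse_validation: float
    n_train: int
    n_validation: int
    split_seed: int


def _check_full_rank(X: pd.DataFrame) -> None:
    A = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    if np.linalg.matrix_rank(A) == A.shape[1]:
        return
    # identify offending columns by greedy rank growth
    bad = []
    cols = [np.ones(len(X))]
    for name in X.columns:
        trial = np.column_stack(cols + [X[name].to_numpy(float)])
        if np.linalg.matrix_rank(trial) == len(cols):
            bad.append(name)
        else:
            cols.append(X[name].to_numpy(float))
    raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_mlr(
    design: pd.DataFrame,
    response: pd.Series | np.ndarray,
    split: float = 0.7,
    seed: int = 0,
) -> tuple[LinearModel, MLRReport]:
    """Ordinary least squares on a seeded train split; metrics on both splits.

    The data are split ``split`` : ``1 - split`` (default 7:3) into training
    and validation; the model is fitted on the training rows only and the
    report carries R^2 and RMSE for both subsets.
    """
    y = np.asarray(response, dtype=float)
    if len(design) != len(y):
        raise ValueError("design and response disagree in length")
    if len(design) <= design.shape[1] + 1:
        raise ValueError(
            f"need more rows ({len(design)}) than predictors + 1 ({design.shape[1] + 1})"
        )
    if not (np.all(np.isfinite(design.to_numpy(float))) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in design or response")
    _check_full_rank(design)
    idx = np.arange(len(design))
    idx_tr, idx_va = train_test_split(idx, train_size=split, random_state=seed)
    X_tr = sm.add_constant(design.iloc[idx_tr], has_constant="add")
    fit = sm.OLS(y[idx_tr], X_tr).fit()

    def _metrics(rows: np.ndarray) -> tuple[float, float]:
        X = sm.add_constant(design.iloc[rows], has_constant="add")
        pred = fit.predict(X)
        resid = y[rows] - pred
        ss_tot = np.sum((y[rows] - y[rows].mean()) ** 2)
        r2 = 1 - np.sum(resid**2) / ss_tot if ss_tot > 0 else float("nan")
        return float(r2), float(np.sqrt(np.mean(resid**2)))

    r2_tr, rmse_tr = _metrics(idx_tr)
    r2_va, rmse_va = _metrics(idx_va)
    model = LinearModel(
        predictor_names=tuple(design.columns),
        coefficients=tuple(float(fit.params[c]) for c in design.columns),
        intercept=float(fit.params["const"]),
        response=getattr(response, "name", None) or "response",
        provenance="fitted",
    )
    report = MLRReport(
        r2_train=r2_tr, rmse_train=rmse_tr,
        r2_validation=r2_va, rmse_validation=rmse_va,
        n_train=len(idx_tr), n_validation=len(idx_va), split_seed=seed,
    )
    return model, report


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Pearson r with pairwise deletion of missing values; (NaN, n) if undefined."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
        return float("nan"), n
    return float(stats.pearsonr(x[ok], y[ok]).statistic), n


def correlate(
    index_table: pd.DataFrame,
    outcomes: pd.DataFrame,
    outcome_cols: Sequence[str] = ("yield_mg_ha", "biomass_mg_ha"),
) -> pd.DataFrame:
    """Per (trait, index, stage, outcome) Pearson correlation across plots.

    ``index_table`` is the long-format battery output (columns plot_id,
    stage, trait, index, value); ``outcomes`` has plot_id plus the outcome
    columns.  Pairs with missing values are dropped pairwise and n is
    reported alongside r (NaN marks undefined correlations).
    """
    merged = index_table.merge(outcomes, on="plot_id", how="inner")
    rows = []
    for (trait, index, stage), grp in merged.groupby(
        ["trait", "index", "stage"], dropna=False, sort=True
    ):
        for col in outcome_cols:
            r, n = pearson(grp["value"].to_numpy(), grp[col].to_numpy())
            rows.append(
                {"trait": trait, "index": index, "stage": stage,
                 "outcome": col, "r": r, "n": n}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cultivar clustering and ANOVA
# ---------------------------------------------------------------------------

def cluster_cultivars(
    means: pd.DataFrame, k: int = 3,
    columns: Sequence[str] = ("yield_mg_ha", "biomass_mg_ha"),
) -> tuple[pd.Series, pd.DataFrame]:
    """Agglomerative (Ward, Euclidean) clustering of cultivars on z-scored
    yield and biomass means; labels C1..Ck ordered by descending mean yield.

    Returns the per-cultivar label Series (same index as ``means``) and a
    per-cluster table of mean yield/biomass and member counts.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(means):
        raise ValueError(f"k = {k} exceeds the {len(means)} cultivars")
    X = means.loc[:, list(columns)].to_numpy(float)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    if k == 1:
        raw = np.ones(len(means), dtype=int)
    else:
        raw = fcluster(linkage(Z, method="ward"), t=k, criterion="maxclust")
    order = (
        pd.Series(X[:, 0]).groupby(raw).mean().sort_values(ascending=False).index
    )
    relabel = {old: f"C{i + 1}" for i, old in enumerate(order)}
    labels = pd.Series([relabel[c] for c in raw], index=means.index, name="cluster")
    table = (
        means.assign(cluster=labels.values)
        .groupby("cluster")[list(columns)]
        .agg(["mean", "count"])
    )
    return labels, table


def anova_oneway(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Classical one-way ANOVA F test; returns (F, p)."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("the grouping factor needs at least two levels")
    samples = [values[groups == g] for g in levels]
    if all(len(s) < 2 for s in samples):
        raise ValueError("at least one group needs two or more observations")
    res = stats.f_oneway(*samples)
    return float(res.statistic), float(res.pvalue)


def anova_twoway(
    data: pd.DataFrame, response: str, factor_a: str, factor_b: str,
    interaction: bool = False,
) -> pd.DataFrame:
    """Two-way ANOVA main effects (type II sums of squares).

    Fitted without interaction by default: with one replicate per cell (one
    uniformity value per cultivar-year) no degrees of freedom remain for an
    interaction term.  Returns the statsmodels ANOVA table (F, PR(>F) per
    factor).
    """
    for f in (factor_a, factor_b):
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than two levels")
    from statsmodels.formula.api import ols

    op = "*" if interaction else "+"
    model = ols(
        f"Q('{response}') ~ C(Q('{factor_a}')) {op} C(Q('{factor_b}'))", data=data
    ).fit()
    return sm.stats.anova_lm(model, typ=2)


# ---------------------------------------------------------------------------
# Sensitivity analyses
# ---------------------------------------------------------------------------

#: Classification-parameter grids of the bin-width sensitivity analysis
#: (PH in cm).
DEFAULT_SWEEP_WIDTHS = {
    "LAI": (0.25, 0.5, 1.0, 1.5, 2.0, 2.5, 3.75, 5.0, 7.5),
    "SPAD": (1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 15.0, 20.0, 30.0, 40.0),
    "PH": (1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 15.0, 20.0, 30.0, 40.0, 50.0),
}

_ENTROPY_INDICES = {
    "shannon": shannon_entropy,
    "pielou": pielou_index,
    "alatalo": alatalo_index,
}


@dataclass
class SweepResult:
    """Correlations of the entropy-based indices along a sensitivity axis.

    ``axis`` is ``"bin_width"`` or ``"gsd"``; ``table`` has one row per
    (axis value, index, outcome) with Pearson r and n (NaN r marks the
    degenerate all-one-class case the sweep is designed to expose).
    """

    axis: str
    axis_values: tuple[float, ...]
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.axis_values, self.axis_values[1:])):
            raise ValueError("axis_values must be strictly increasing")

    def r(self, index: str, axis_value: float, outcome: str = "yield_mg_ha") -> float:
        t = self.table
        row = t[(t["index"] == index) & (t["axis_value"] == axis_value)
                & (t["outcome"] == outcome)]
        return float(row["r"].iloc[0])


def _entropy_indices_per_plot(
    values_per_plot: Mapping[str, np.ndarray], width: float, origin: float
) -> pd.DataFrame:
    rows = {}
    for plot, vals in values_per_plot.items():
        dist = bin_values(vals, width, origin)
        rows[plot] = {name: fn(dist) for name, fn in _ENTROPY_INDICES.items()}
    return pd.DataFrame.from_dict(rows, orient="index")


def sweep_bin_width(
    plot_values: Mapping[str, np.ndarray] | Mapping[str, TraitRaster],
    outcomes: pd.DataFrame,
    widths: Sequence[float],
    origin: float = 0.0,
    outcome_cols: Sequence[str] = ("yield_mg_ha", "biomass_mg_ha"),
) -> SweepResult:
    """Recompute Shannon/Pielou/Alatalo per classification parameter and
    correlate each with the outcomes.

    ``plot_values`` maps plot_id to that plot's valid trait values (or a
    TraitRaster, from which valid values are taken); ``outcomes`` is indexed
    by the same plot ids via its ``plot_id`` column.
    """
    vals = {
        p: (v.valid_values() if isinstance(v, TraitRaster) else np.asarray(v, float))
        for p, v in plot_values.items()
    }
    out = outcomes.set_index("plot_id")
    rows = []
    for w in widths:
        per_plot = _entropy_indices_per_plot(vals, w, origin)
        aligned = per_plot.join(out, how="inner")
        for index in _ENTROPY_INDICES:
            for col in outcome_cols:
                r, n = pearson(aligned[index].to_numpy(), aligned[col].to_numpy())
                rows.append({"axis_value": float(w), "index": index,
                             "outcome": col, "r": r, "n": n})
    return SweepResult(
        axis="bin_width", axis_values=tuple(sorted(float(w) for w in widths)),
        table=pd.DataFrame(rows),
    )


def degrade_resolution(raster: TraitRaster, factor: int) -> TraitRaster:
    """Coarsen a raster by non-overlapping ``factor`` x ``factor`` block means.

    Block means are taken over valid pixels only; a block with no valid pixel
    becomes invalid; trailing rows/columns that do not fill a block are
    dropped; the GSD is multiplied by ``factor``.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return replace(raster, values=raster.values.copy(), mask=raster.mask.copy())
    ny, nx = raster.shape
    ny2, nx2 = ny // factor, nx // factor
    if ny2 == 0 or nx2 == 0:
        raise ValueError(f"factor {factor} exceeds raster shape {raster.shape}")
    v = np.where(raster.mask, raster.values, 0.0)[: ny2 * factor, : nx2 * factor]
    m = raster.mask[: ny2 * factor, : nx2 * factor]
    v = v.reshape(ny2, factor, nx2, factor)
    m = m.reshape(ny2, factor, nx2, factor)
    counts = m.sum(axis=(1, 3))
    sums = v.sum(axis=(1, 3))
    out = np.zeros((ny2, nx2))
    np.divide(sums, counts, out=out, where=counts > 0)
    return TraitRaster(
        values=out, mask=counts > 0, gsd_m=raster.gsd_m * factor,
        trait=raster.trait, plot_id=raster.plot_id, stage=raster.stage,
    )


def sweep_gsd(
    plot_rasters: Mapping[str, TraitRaster],
    outcomes: pd.DataFrame,
    factors: Sequence[int] = (1, 2, 4, 8),
    bin_width: float | None = None,
    origin: float = 0.0,
    outcome_cols: Sequence[str] = ("yield_mg_ha", "biomass_mg_ha"),
) -> SweepResult:
    """Correlations of the entropy indices after GSD degradation.

    Each plot raster is block-averaged by every factor (e.g. 3 cm native GSD
    degraded to 6, 12 and 24 cm), the entropy battery recomputed at the fixed
    classification parameter, and correlated with the outcomes.
    """
    from .uniformity import DEFAULT_BIN_WIDTHS

    some = next(iter(plot_rasters.values()))
    if bin_width is None:
        bin_width = DEFAULT_BIN_WIDTHS[some.trait]
    out = outcomes.set_index("plot_id")
    rows = []
    for f in factors:
        vals = {
            p: degrade_resolution(r, int(f)).valid_values()
            for p, r in plot_rasters.items()
        }
        per_plot = _entropy_indices_per_plot(vals, bin_width, origin)
        aligned = per_plot.join(out, how="inner")
        gsd = some.gsd_m * int(f)
        for index in _ENTROPY_INDICES:
            for col in outcome_cols:
                r, n = pearson(aligned[index].to_numpy(), aligned[col].to_numpy())
                rows.append({"axis_value": gsd, "index": index,
                             "outcome": col, "r": r, "n": n})
    return SweepResult(
        axis="gsd",
        axis_values=tuple(some.gsd_m * int(f) for f in sorted(factors)),
        table=pd.DataFrame(rows),
    )
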