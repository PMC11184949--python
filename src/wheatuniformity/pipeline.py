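"""End-to-end pipeline: simulate -> traits -> uniformity battery -> association.

Drives the whole method on a synthetic field: per stage, two-band scenes are
simulated and segmented (valley NDVI threshold pooled over plots), trait
surfaces simulated and summarised into the 24-statistic battery, outcomes
generated from the flowering-stage LAI mean and Pielou index, correlations
and a small MLR fitted, and every table written to the output directory.

Reruns with the same configuration and seed reproduce every output file
byte for byte (outputs carry no timestamps; all randomness is keyed on the
configured seeds).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .assoc import correlate, fit_mlr
from .io import write_model
from .raster import STAGES
from .synth import FieldSimConfig, simulate_spectral_scene, simulate_trait_raster, simulate_yield_table
from .traits import compute_fvc, compute_ndvi, find_valley_threshold
from .uniformity import DEFAULT_BIN_WIDTHS, full_battery, records_to_frame

log = logging.getLogger("wheatuniformity")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    sim: FieldSimConfig = field(default_factory=FieldSimConfig)
    stages: tuple[str, ...] = STAGES
    bin_widths: dict = field(default_factory=lambda: dict(DEFAULT_BIN_WIDTHS))
    ndvi_threshold: float | str = "auto"
    percentile: float = 97.0
    split_seed: int = 0
    use_crop_mask: bool = True

    def __post_init__(self) -> None:
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages {bad}; valid: {STAGES}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline and write all result tables to ``out_dir``.

    Writes ``uniformity.csv`` (long-format battery), ``outcomes.csv``,
    ``correlations.csv``, ``threshold.json``, fitted model JSONs and
    ``run_log.json`` (version, config hash, seeds).  Returns ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = cfg.sim
    log.info("pipeline start: %d plots, stages %s, seed %d",
             sim.n_plots, cfg.stages, sim.seed)

    # --- stage 1: spectral scenes and NDVI -------------------------------
    ndvi = {}  # (stage, plot) -> raster
    for stage in cfg.stages:
        for p in range(sim.n_plots):
            sc = simulate_spectral_scene(sim, p, stage=stage)
            ndvi[stage, p] = compute_ndvi(sc.red, sc.nir)

    # --- stage 2: segmentation threshold ----------------------------------
    if cfg.ndvi_threshold == "auto":
        pooled = [
            np.concatenate(
                [ndvi[stage, p].valid_values() for p in range(sim.n_plots)]
            )
            for stage in cfg.stages
        ]
        thr_res = find_valley_threshold(pooled, stage_labels=list(cfg.stages))
        threshold = thr_res.threshold
        valleys = thr_res.per_stage_valleys
    else:
        threshold = float(cfg.ndvi_threshold)
        valleys = []
    (out / "threshold.json").write_text(
        json.dumps({"threshold": threshold, "per_stage_valleys": valleys}, indent=1)
    )
    log.info("NDVI threshold: %.4f", threshold)

    # --- stage 3: traits and battery --------------------------------------
    records = []
    lai_fs = {}  # plot -> (mean LAI, Pielou LAI) at flowering for outcome generation
    from .uniformity import bin_values, pielou_index

    for stage in cfg.stages:
        for p in range(sim.n_plots):
            plot_id = f"plot_{p:03d}"
            fvc, crop_mask = compute_fvc(ndvi[stage, p], threshold)
            rasters = {
                t: simulate_trait_raster(sim, t, p, stage=stage)
                for t in ("LAI", "SPAD", "PH")
            }
            recs = full_battery(
                rasters, crop_mask, bin_widths=cfg.bin_widths,
                use_crop_mask=cfg.use_crop_mask,
            )
            records.extend(recs)
            if stage == "FS" or (stage == cfg.stages[-1] and "FS" not in cfg.stages):
                vals = rasters["LAI"].valid_values()
                lai_fs[plot_id] = (
                    float(vals.mean()),
                    pielou_index(bin_values(vals, cfg.bin_widths["LAI"])),
                )

    table = records_to_frame(records)
    table.to_csv(out / "uniformity.csv", index=False)

    # --- stage 4: outcomes -------------------------------------------------
    plot_ids = sorted(lai_fs)
    outcomes = simulate_yield_table(
        sim,
        uniformity_values=np.array([lai_fs[p][1] for p in plot_ids]),
        trait_means=np.array([lai_fs[p][0] for p in plot_ids]),
        plot_ids=plot_ids,
    )
    outcomes.to_csv(out / "outcomes.csv", index=False)

    # --- stage 5: association ---------------------------------------------
    corr = correlate(table, outcomes)
    corr.to_csv(out / "correlations.csv", index=False)

    fitted = {}
    wide = table.pivot_table(
        index="plot_id", columns=["abbreviation", "stage"], values="value"
    )
    wide.columns = [f"{a}_{s}" for a, s in wide.columns]
    if sim.n_plots >= 20:
        preds = [f"{a}_{s}" for a in ("FE", "LJ", "SJ", "PM")
                 for s in ("JS", "FS", "LFS") if f"{a}_{s}" in wide.columns]
    else:
        preds = [c for c in ("FE_FS", "LJ_FS", "SJ_FS", "PM_FS") if c in wide.columns]
    design = wide.loc[outcomes["plot_id"], preds]
    constant = [c for c in design.columns if np.ptp(design[c].to_numpy()) == 0]
    if constant:
        log.info("dropping zero-variance predictors: %s", constant)
        design = design.drop(columns=constant)
        preds = [p for p in preds if p not in constant]
    for response in ("yield_mg_ha", "biomass_mg_ha"):
        if len(design) > len(preds) + 1 and preds:
            try:
                model, report = fit_mlr(
                    design.reset_index(drop=True),
                    outcomes[response], seed=cfg.split_seed,
                )
            except ValueError as exc:  # e.g. collinear on tiny fields
                log.warning("MLR for %s skipped: %s", response, exc)
                continue
            write_model(model, out / f"model_{response}.json")
            fitted[response] = asdict(report)

    (out / "run_log.json").write_text(
        json.dumps(
            {
                "package_version": __version__,
                "config_hash": cfg.config_hash(),
                "config": cfg.to_dict(),
                "seeds": {"simulation": sim.seed, "split": cfg.split_seed},
                "threshold": threshold,
                "n_records": len(records),
                "mlr_reports": fitted,
            },
            indent=1,
            default=str,
        )
    )
    log.info("pipeline done: %d records -> %s", len(records), out)
    return out
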