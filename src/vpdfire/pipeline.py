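"""End-to-end orchestration: synthesize -> fit -> thresholds -> flammable
days -> trends -> attribution, with artifacts and a reproducible report.

Every artifact that carries results (threshold CSV, attribution JSON,
trend CSVs) is written deterministically: identical config + seed gives
byte-identical files.  Timestamps live only in the run report.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import __version__
from .climate import add_vpd, regional_mean
from .config import IGNITION_TYPES, RunConfig
from .flammability import count_flammable_days, trend_map, wilcoxon_compare
from .random import substream, substream_seed
from .synthetic import (generate_climate_grid, generate_covariates,
                        generate_esm_ensemble, generate_fire_catalog,
                        truth_manifest)
from .threshold import (FireThresholdModel, compare_thresholds,
                        label_large_small)
from .attribution import AttributionModel

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    pass


@dataclass
class RunReport:
    """Per-stage status, artifact inventory and provenance of one run."""

    config_echo: dict
    seed: int
    version: str = __version__
    stages: dict = field(default_factory=dict)
    artifacts: list = field(default_factory=list)
    config_hash: str = ""

    def mark(self, stage: str, status: str, elapsed: float, **extra) -> None:
        self.stages[stage] = {"status": status, "elapsed_s": round(elapsed, 3), **extra}

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True, default=str)


def validate_config(path) -> RunConfig:
    """Load and schema-check a YAML run config; raises with itemized errors."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    from pydantic import ValidationError

    try:
        return RunConfig(**raw)
    except ValidationError as err:
        lines = [f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in err.errors()]
        raise ValueError("invalid run config:\n  " + "\n  ".join(lines)) from err


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(config.model_dump_json().encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


STAGE_ORDER = ("simulate", "fit", "thresholds", "flamdays", "attribute")


def run_pipeline(config: RunConfig, outdir: Optional[Path] = None,
                 report_path: Optional[Path] = None,
                 stop_after: Optional[str] = None) -> RunReport:
    """Execute the stages (optionally up to ``stop_after``); returns the report.

    A stage failure marks the stage in the report, skips the rest, and
    re-raises as :class:`StageError`.
    """
    outdir = Path(outdir or config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_echo=json.loads(config.model_dump_json()),
                       seed=config.seed, config_hash=_config_hash(config))
    logger.info("run %s seed=%d outdir=%s", report.config_hash, config.seed, outdir)

    def _artifact(path: Path) -> None:
        report.artifacts.append(str(path))

    fns = {"simulate": _stage_simulate, "fit": _stage_fit,
           "thresholds": _stage_thresholds, "flamdays": _stage_flamdays,
           "attribute": _stage_attribute}
    if stop_after is not None and stop_after not in STAGE_ORDER:
        raise ValueError(f"unknown stage {stop_after!r}")
    state: dict = {}
    try:
        for name in STAGE_ORDER:
            _stage(report, name, fns[name], config, outdir, state, _artifact)
            if name == stop_after:
                break
    finally:
        if report_path is None:
            report_path = outdir / "run_report.json"
        report_path.write_text(report.to_json())
    return report


def _stage(report, name, fn, config, outdir, state, artifact) -> None:
    t0 = time.perf_counter()
    try:
        extra = fn(config, outdir, state, artifact) or {}
    except Exception as err:
        report.mark(name, "failed", time.perf_counter() - t0, error=str(err))
        raise StageError(f"stage {name!r} failed: {err}") from err
    report.mark(name, "ok", time.perf_counter() - t0, **extra)


def _stage_simulate(config: RunConfig, outdir: Path, state: dict, artifact) -> dict:
    syn = config.synthetic.model_copy(update={"seed": config.seed})
    climate = generate_climate_grid(syn)
    covariates = generate_covariates(syn)
    catalog = generate_fire_catalog(climate, covariates, syn)
    ensemble = generate_esm_ensemble(syn)
    manifest = truth_manifest(syn, p_level=config.p_level)
    state.update(syn=syn, climate=climate, covariates=covariates,
                 catalog=catalog, ensemble=ensemble, manifest=manifest)

    climate_path = outdir / "climate.nc"
    climate.to_netcdf(climate_path, engine="scipy")
    cat_path = outdir / "fire_catalog.csv"
    cat = catalog.copy()
    cat["discovery_date"] = pd.DatetimeIndex(cat["discovery_date"]).strftime("%Y-%m-%d")
    _write_csv(cat, cat_path)
    manifest_path = outdir / "truth_manifest.json"
    manifest_path.write_text(manifest.to_json())
    for p in (climate_path, cat_path, manifest_path):
        artifact(p)
    return {"n_events": int(len(catalog))}


def _stage_fit(config: RunConfig, outdir: Path, state: dict, artifact) -> dict:
    syn = state["syn"]
    catalog = state["catalog"]
    if config.label_source == "size_percentile":
        labelled = label_large_small(catalog, config.percentile)
    else:
        labelled = catalog[catalog["cause"].isin(IGNITION_TYPES)]
    results = {}
    diags = {}
    for k, kind in enumerate(IGNITION_TYPES):
        model = FireThresholdModel.from_catalog(
            labelled, state["climate"], state["covariates"], kind,
            factors=config.fit_factors, convention=config.vpd_convention)
        res = model.fit(config=config.mcmc,
                        seed=substream_seed(config.seed, "mcmc", k))
        res.save(outdir / f"posterior_{kind}.nc")
        artifact(outdir / f"posterior_{kind}.nc")
        results[kind] = res
        diags[kind] = res.diagnostics
    state["fits"] = results
    fit_report = {
        "diagnostics": {k: {kk: (bool(vv) if isinstance(vv, (bool, np.bool_)) else float(vv))
                            for kk, vv in d.items()} for k, d in diags.items()},
        "sampler": config.mcmc.model_dump(),
        "factors": list(config.fit_factors),
        "label_source": config.label_source,
        "percentile": config.percentile,
    }
    path = outdir / "fit_report.json"
    path.write_text(json.dumps(fit_report, indent=2, sort_keys=True))
    artifact(path)
    return {"failed_fits": sum(d["failed"] for d in diags.values())}


def _stage_thresholds(config: RunConfig, outdir: Path, state: dict, artifact) -> dict:
    fits = state["fits"]
    frames = [fits[k].vpd_threshold(config.p_level) for k in IGNITION_TYPES]
    thresholds = pd.concat(frames, ignore_index=True)
    tag = f"p{int(round(config.percentile * 100)):02d}"
    thr_path = outdir / f"thresholds_{tag}.csv"
    _write_csv(thresholds, thr_path)
    comparison = compare_thresholds(fits["human"], fits["lightning"], config.p_level)
    cmp_path = outdir / f"threshold_comparison_{tag}.csv"
    _write_csv(comparison, cmp_path)
    artifact(thr_path)
    artifact(cmp_path)
    state["thresholds"] = thresholds
    return {"n_thresholds": int(len(thresholds))}


def _stage_flamdays(config: RunConfig, outdir: Path, state: dict, artifact) -> dict:
    climate = add_vpd(state["climate"])
    thresholds = state["thresholds"]
    panels = {}
    summaries = []
    for kind in IGNITION_TYPES:
        sub = thresholds[thresholds["ignition_type"] == kind]
        thr = dict(zip(sub["ecoregion_id"].astype(int), sub["vpd_t"]))
        panel = count_flammable_days(climate["vpd"], thr, climate["ecoregion"])
        panels[kind] = panel
        trends = trend_map(panel)
        regional = regional_mean(panel)
        summaries.append({
            "ignition_type": kind,
            "mean_days_per_year": float(regional.mean()),
            "regional_trend_days_per_year": float(np.median(trends["slope"].values)),
            "frac_cells_significant": float(trends["significant"].values.mean()),
        })
        ds = xr.Dataset({"flammable_days": panel})
        ds.to_netcdf(outdir / f"flammable_days_{kind}.nc", engine="scipy")
        trends.to_netcdf(outdir / f"trends_{kind}.nc", engine="scipy")
        artifact(outdir / f"flammable_days_{kind}.nc")
        artifact(outdir / f"trends_{kind}.nc")
    stat, p = wilcoxon_compare(
        panels["human"].mean("year").values.ravel(),
        panels["lightning"].mean("year").values.ravel())
    summary = pd.DataFrame(summaries)
    path = outdir / "flammable_days_summary.csv"
    _write_csv(summary, path)
    artifact(path)
    state["panels"] = panels
    state["flam_summary"] = summary
    state["wilcoxon_hm_vs_ltn"] = {"statistic": stat, "p": p}
    return {"wilcoxon_p": p}


def _stage_attribute(config: RunConfig, outdir: Path, state: dict, artifact) -> dict:
    ensemble = state["ensemble"]
    results = {}
    for kind in IGNITION_TYPES:
        y = regional_mean(state["panels"][kind])
        for d, design in enumerate(config.designs):
            rng = substream(config.seed, "rof", index=len(config.designs) * (0 if kind == "human" else 1) + d)
            model = AttributionModel(y, ensemble, design=design,
                                     window_years=config.rof.window_years,
                                     baseline=(list(range(config.anomaly_baseline[0], config.anomaly_baseline[1] + 1))
                                               if config.anomaly_baseline else None),
                                     mc_draws=config.rof.mc_draws)
            res = model.fit(rng=rng)
            results[f"{kind}.{design}"] = res
    payload = {key: json.loads(res.to_json()) for key, res in results.items()}
    path = outdir / "attribution.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    artifact(path)
    rows = []
    for key, res in results.items():
        kind, design = key.split(".")
        tab = res.summary().assign(ignition_type=kind, design=design)
        rows.append(tab)
    _write_csv(pd.concat(rows, ignore_index=True), outdir / "attribution_summary.csv")
    artifact(outdir / "attribution_summary.csv")
    state["attribution"] = results
    return {"n_regressions": len(results)}
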