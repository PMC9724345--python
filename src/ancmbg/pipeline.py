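"""End-to-end orchestration of one country-stratum analysis.

One run covers one equity stratum (or the overall population): filter the
survey, select covariates with the non-spatial GLM, fit the binomial
geostatistical model, simulate the coverage surface, compute exceedance
probabilities against the policy target, aggregate by district, validate
the fitted correlation structure, and write everything with a manifest of
checksums so reruns are verifiable.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregate as agg
from . import exploratory, predict, validate
from .geostat import MaternParams, ModelSpec, fit as fit_model
from .grids import GridSurface
from .regions import read_districts, write_districts
from .survey import SurveyDataset, STRATA_LEVELS
from .synthetic import (LandscapeConfig, TruthParams, generate_landscape,
                        simulate_survey)

__all__ = ["RunConfig", "RunManifest", "PipelineError",
           "InsufficientDataError", "run_stratified", "compare_strata"]

STRATIFIERS = (["overall"]
               + [f"{k}:{v}" for k, levels in STRATA_LEVELS.items()
                  for v in levels])


class PipelineError(RuntimeError):
    """A pipeline stage failed."""


class InsufficientDataError(PipelineError):
    """The stratum has too few clusters for spatial modelling."""


@dataclass
class RunConfig:
    """Settings of one stratified run (YAML-loadable)."""

    seed: int
    outdir: str
    stratifier: str = "overall"
    threshold: float = 0.70
    n_draws: int = 1000
    n_simulations: int = 1000
    nu: float = 1.0
    min_clusters: int = 10
    synthetic: dict | None = None
    inputs: dict | None = None

    def __post_init__(self) -> None:
        if self.stratifier not in STRATIFIERS:
            raise ValueError(f"stratifier must be one of {STRATIFIERS}")
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("give exactly one of 'synthetic' or 'inputs'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass
class RunManifest:
    config: dict
    version: str
    timings_s: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)      # path -> sha256
    inputs: dict = field(default_factory=dict)
    converged: bool = False
    envelope_compatible: bool | None = None
    envelope_bins_outside: int | None = None
    dropped_fraction: float = 0.0
    n_clusters: int = 0
    selected_covariates: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1,
                                         sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(config: RunConfig, outdir: Path):
    """Return (dataset, districts, pregnancy grid, covariate grids)."""
    if config.synthetic is not None:
        syn = dict(config.synthetic)
        lc = LandscapeConfig(**syn.get("landscape", {}))
        tr = dict(syn.get("truth", {}))
        truth = TruthParams(
            beta=np.asarray(tr.get("beta", [0.85, 0.5])),
            covariates=list(tr.get("covariates", ["ntl"])),
            matern=MaternParams(sigma2=tr.get("sigma2", 1.0),
                                phi=tr.get("phi", 15.0),
                                nu=tr.get("nu", 1.0),
                                tau2=tr.get("tau2", 0.1)))
        rng = np.random.default_rng(config.seed)
        land_seed = int(rng.integers(2 ** 31))
        survey_seed = int(rng.integers(2 ** 31))
        landscape = generate_landscape(lc, seed=land_seed)
        dataset = simulate_survey(landscape, truth,
                                  n_clusters=syn.get("n_clusters", 150),
                                  n_per_cluster=syn.get("n_per_cluster", 25),
                                  seed=survey_seed)
        inp = outdir / "inputs"
        inp.mkdir(parents=True, exist_ok=True)
        dataset.to_csv(inp / "survey.csv")
        write_districts(inp / "districts.geojson", landscape.districts)
        landscape.pregnancy_raster.write_ascii(inp / "pregnancies.asc")
        for name, ras in landscape.covariate_rasters.items():
            ras.write_ascii(inp / f"cov_{name}.asc")
        np.savetxt(inp / "facilities.csv", landscape.facilities,
                   delimiter=",", header="x,y", comments="")
        return (dataset, landscape.districts, landscape.pregnancy_raster,
                dict(landscape.covariate_rasters))

    paths = config.inputs
    dataset = SurveyDataset.from_csv(paths["survey_csv"])
    districts = read_districts(paths["districts"])
    pregnancies = GridSurface.read_ascii(paths["pregnancies"])
    cov_grids = {name: GridSurface.read_ascii(p)
                 for name, p in paths.get("covariates", {}).items()}
    return dataset, districts, pregnancies, cov_grids


def run_stratified(config: RunConfig) -> RunManifest:
    """Run the full analysis for one stratum; see module docstring."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.__dict__.copy(), version="0.1.0")
    t_all = time.time()

    def staged(name):
        t0 = time.time()

        def done():
            manifest.timings_s[name] = round(time.time() - t0, 3)
        return done

    try:
        done = staged("inputs")
        dataset, districts, pregnancies, cov_grids = _load_inputs(config,
                                                                  outdir)
        done()

        # stratum filter + missingness handling
        done = staged("filter")
        if config.stratifier != "overall":
            strat, level = config.stratifier.split(":")
            dataset, dropped = dataset.drop_missing(["n_anc4", strat])
            dataset = dataset.filter_stratum(strat, level)
        else:
            dataset, dropped = dataset.drop_missing(["n_anc4"])
        manifest.dropped_fraction = float(dropped)
        manifest.n_clusters = dataset.n_clusters
        if dataset.n_clusters < config.min_clusters:
            raise InsufficientDataError(
                f"stratum {config.stratifier!r} has {dataset.n_clusters} "
                f"clusters; need at least {config.min_clusters}")
        done()

        done = staged("select")
        selection = exploratory.select_covariates(dataset)
        manifest.selected_covariates = selection.selected
        pd.DataFrame(selection.steps).to_json(outdir / "selection.json",
                                              orient="records", indent=1)
        done()

        done = staged("fit")
        spec = ModelSpec(covariates=selection.selected, nu=config.nu,
                         threshold=config.threshold)
        fr = fit_model(dataset, spec, seed=config.seed)
        fr.to_json(outdir / "fit.json")
        manifest.converged = bool(fr.converged)
        done()
        if not fr.converged:
            raise PipelineError("model fit did not converge")

        done = staged("predict")
        template = pregnancies.full_like(0.0)
        samples = predict.conditional_simulate(
            fr, dataset, template, cov_grids,
            n_draws=config.n_draws, seed=config.seed)
        mean, se, lo, hi = predict.summarize_surface(samples)
        ep = predict.exceedance_probability(samples, config.threshold)
        for name, ras in [("mean", mean), ("se", se), ("lower95", lo),
                          ("upper95", hi), ("exceedance", ep)]:
            ras.write_ascii(outdir / f"coverage_{name}.asc")
        done()

        done = staged("aggregate")
        summaries = agg.district_aggregate(samples, pregnancies, districts,
                                           config.threshold)
        frame = agg.summaries_to_frame(summaries)
        frame.to_csv(outdir / "district_summaries.csv", index=False,
                     float_format="%.10g")
        done()

        done = staged("validate")
        env = validate.variogram_envelope(fr, dataset,
                                          n_simulations=config.n_simulations,
                                          seed=config.seed)
        env_frame = env.variogram.to_frame()
        env_frame["lower95"] = env.lower
        env_frame["upper95"] = env.upper
        env_frame.to_csv(outdir / "envelope.csv", index=False,
                         float_format="%.10g")
        manifest.envelope_compatible = bool(env.compatible)
        manifest.envelope_bins_outside = len(env.bins_outside)
        done()

        manifest.timings_s["total"] = round(time.time() - t_all, 3)
        for p in sorted(outdir.rglob("*")):
            if p.is_file() and p.name != "manifest.json":
                manifest.outputs[str(p.relative_to(outdir))] = _sha256(p)
        manifest.to_json(outdir / "manifest.json")
        return manifest
    except PipelineError:
        # keep the manifest for diagnosis, drop partial products
        manifest.timings_s["total"] = round(time.time() - t_all, 3)
        for p in sorted(outdir.rglob("*")):
            if p.is_file() and p.name not in ("manifest.json",) \
                    and not str(p.relative_to(outdir)).startswith("inputs"):
                p.unlink()
        manifest.to_json(outdir / "manifest.json")
        raise


def compare_strata(dir_a: str | Path, dir_b: str | Path,
                   threshold: float = 0.70):
    """Equity comparison of two runs on the same districts.

    Returns (per-district DataFrame, summary dict) with coverage
    difference/ratio per district, counts of districts above the target
    in each arm, and the fold-ratio of those counts.
    """
    fa = pd.read_csv(Path(dir_a) / "district_summaries.csv")
    fb = pd.read_csv(Path(dir_b) / "district_summaries.csv")
    if not (fa["district_id"].to_numpy() == fb["district_id"].to_numpy()).all():
        raise ValueError("district ids do not match between runs")
    out = pd.DataFrame({
        "district_id": fa["district_id"],
        "coverage_a": fa["coverage_mean"],
        "coverage_b": fb["coverage_mean"],
        "difference": fa["coverage_mean"] - fb["coverage_mean"],
        "ratio": fa["coverage_mean"] / fb["coverage_mean"],
        "ep_a": fa["exceedance_probability"],
        "ep_b": fb["exceedance_probability"],
    })
    above_a = int((fa["coverage_mean"] > threshold).sum())
    above_b = int((fb["coverage_mean"] > threshold).sum())
    summary = {
        "districts": int(len(fa)),
        "above_threshold_a": above_a,
        "above_threshold_b": above_b,
        "fold_ratio": (above_a / above_b) if above_b else np.inf,
        "mean_difference": float(out["difference"].mean()),
    }
    return out, summary
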