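"""End-to-end orchestration: simulate/load -> preprocess -> model -> screen -> enrich.

A single validated config drives all five stages for one fluid, with a
global seed making every numeric output reproducible.  Each run writes a
manifest (config hash, stage outputs, per-comparison model summaries,
counts) so results can be audited and stages rerun in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from . import __version__, chemo, enrich, screen, spectra, synth

log = logging.getLogger("gestox")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EffectItem(_Block):
    metabolite: str
    day: str
    fold_change: float


class SimulateBlock(_Block):
    n_per_cell: int = 8
    points: int = 16384
    noise_sd: float = 0.5
    shift_jitter_sd: float = 0.002
    baseline_amplitude: float = 2.0
    dilution_cv: float = 0.3
    sigma_log: float = 0.15
    effects: list[EffectItem] = []


class PreprocessBlock(_Block):
    bin_spacing: Optional[float] = None  # fluid default: 0.002 plasma / 0.005 urine
    normalize: Optional[str] = None  # fluid default: none plasma / pqn urine
    calibrate: bool = True
    assignments: Optional[str] = None  # YAML AssignmentMap; default derived from library


class ModelBlock(_Block):
    n_orth: int = 1
    folds: int = 7
    n_perm: int = 200


class ScreenBlock(_Block):
    alpha: float = 0.05
    r_rule: Optional[float] = None  # None -> critical_r(alpha, n-2) per comparison
    vip_top: float = 0.10
    report_r_df: int = 7


class EnrichBlock(_Block):
    enabled: bool = True
    pathways: Optional[str] = None  # GMT path; default = packaged demo set


class RunConfig(_Block):
    fluid: Literal["plasma", "urine"]
    mode: Literal["synthetic", "spectra"]
    seed: Optional[int] = None
    spectra_dir: Optional[str] = None
    out_dir: str = "gestox_run"
    simulate: SimulateBlock = SimulateBlock()
    preprocess: PreprocessBlock = PreprocessBlock()
    model: ModelBlock = ModelBlock()
    screen: ScreenBlock = ScreenBlock()
    enrich: EnrichBlock = EnrichBlock()

    @model_validator(mode="after")
    def _check_mode(self) -> "RunConfig":
        if self.mode == "synthetic" and self.seed is None:
            raise ValueError("synthetic mode requires a seed")
        if self.mode == "spectra":
            if self.spectra_dir is None:
                raise ValueError("spectra mode requires spectra_dir")
            if not Path(self.spectra_dir).is_dir():
                raise ValueError(f"spectra_dir {self.spectra_dir!r} does not exist")
        return self

    def bin_spacing(self) -> float:
        if self.preprocess.bin_spacing is not None:
            return self.preprocess.bin_spacing
        return spectra.PLASMA_SPACING if self.fluid == "plasma" else spectra.URINE_SPACING

    def normalization(self) -> str:
        if self.preprocess.normalize is not None:
            return self.preprocess.normalize
        return "none" if self.fluid == "plasma" else "pqn"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _format_validation_error(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = "/" + "/".join(str(x) for x in err["loc"])
        parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run config, injecting defaults.

    Unknown keys are rejected; errors name the offending key with a
    JSON-pointer-style path.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise PipelineError("config", f"{path}: expected a mapping at top level")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise PipelineError("config", f"{path}: {_format_validation_error(exc)}") from exc


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)  # stage -> {inputs, outputs}
    models: dict = field(default_factory=dict)  # comparison label -> summary
    counts: dict = field(default_factory=dict)
    status: str = "OK"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "config_hash": self.config_hash, "version": self.version,
            "status": self.status, "stages": self.stages,
            "models": self.models, "counts": self.counts,
        }, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_acquire(config: RunConfig, out: Path, manifest: RunManifest):
    if config.mode == "synthetic":
        sim = config.simulate
        design = synth.CohortDesign(
            fluid=config.fluid, n_per_cell=sim.n_per_cell, points=sim.points,
            noise_sd=sim.noise_sd, shift_jitter_sd=sim.shift_jitter_sd,
            baseline_amplitude=sim.baseline_amplitude, dilution_cv=sim.dilution_cv)
        effects = synth.EffectSpec(tuple(
            synth.Effect(e.metabolite, e.day, e.fold_change) for e in sim.effects))
        cohort, truth = synth.simulate_cohort(design, effects, seed=config.seed,
                                              sigma_log=sim.sigma_log)
        truth_path = out / "truth.csv"
        truth.to_csv(truth_path)
        manifest.stages["simulate"] = {
            "outputs": [str(truth_path)], "n_spectra": len(cohort)}
        log.info("simulate: %d spectra (%s, seed=%s)", len(cohort), config.fluid, config.seed)
        return cohort, synth.build_default_library(config.fluid)
    paths = sorted(Path(config.spectra_dir).glob("*.csv")) + \
        sorted(Path(config.spectra_dir).glob("*.jdx"))
    paths = [p for p in paths if p.name not in ("truth.csv",)]
    cohort = []
    for p in paths:
        try:
            cohort.append(spectra.read_spectrum(p))
        except spectra.SpectrumError as exc:
            raise PipelineError("acquire", f"failed reading {p}: {exc}") from exc
    if not cohort:
        raise PipelineError("acquire", f"no spectra found in {config.spectra_dir}")
    manifest.stages["acquire"] = {"inputs": [str(p) for p in paths]}
    return cohort, synth.build_default_library(config.fluid)


def _stage_preprocess(config: RunConfig, cohort, library, out: Path,
                      manifest: RunManifest) -> spectra.FeatureMatrix:
    bin_spec = spectra.BinSpec.for_fluid(config.fluid, spacing=config.bin_spacing())
    rows = []
    for sp in cohort:
        try:
            if config.preprocess.calibrate:
                sp = spectra.calibrate(sp)
            rows.append(spectra.bin_spectrum(sp, bin_spec))
        except spectra.SpectrumError as exc:
            raise PipelineError("preprocess",
                                f"sample {sp.meta.sample_id}: {exc}") from exc
    matrix = spectra.assemble_matrix(rows)
    matrix = spectra.normalize(matrix, config.normalization())
    if config.preprocess.assignments:
        amap = spectra.AssignmentMap.from_yaml(config.preprocess.assignments)
    else:
        amap = synth.default_assignment_map(library, fluid=config.fluid)
    try:
        quantified = spectra.quantify_metabolites(matrix, amap)
    except spectra.SpectrumError as exc:
        raise PipelineError("preprocess", str(exc)) from exc
    matrix_path = out / "matrix.csv"
    quant_path = out / "metabolites.csv"
    matrix.to_csv(matrix_path)
    quantified.to_csv(quant_path)
    manifest.stages["preprocess"] = {
        "outputs": [str(matrix_path), str(quant_path)],
        "n_bins": matrix.n_features, "n_metabolites": quantified.n_features,
        "normalization": config.normalization(), "bin_spacing": config.bin_spacing()}
    log.info("preprocess: %d bins -> %d metabolites (%s normalization)",
             matrix.n_features, quantified.n_features, config.normalization())
    return quantified


def _stage_model_screen(config: RunConfig, quantified: spectra.FeatureMatrix,
                        out: Path, manifest: RunManifest):
    models_dir = out / "models"
    volcano_dir = out / "volcano"
    models_dir.mkdir(exist_ok=True)
    volcano_dir.mkdir(exist_ok=True)
    # descriptive all-day PCA trajectory (drives no screening decision)
    scaled_all, _ = chemo.scale(quantified, "center")
    n_pc = min(2, quantified.n_samples - 1, quantified.n_features)
    pca = chemo.fit_pca(scaled_all.values.to_numpy(dtype=float), n_pc)
    pca_df = pd.DataFrame(pca.scores, index=quantified.values.index,
                          columns=[f"PC{k + 1}" for k in range(n_pc)])
    pca_df = pd.concat([quantified.meta, pca_df], axis=1)
    pca_path = out / "pca_scores.csv"
    pca_df.to_csv(pca_path)
    manifest.models["pca_trajectory"] = chemo.model_summary(pca)

    comparisons = {}
    cells = {}
    seed = config.seed if config.seed is not None else 0
    for i, day in enumerate(spectra.DAYS):
        if (quantified.meta["day"] == day).sum() == 0:
            continue
        try:
            res = screen.compare_groups(
                quantified, day, n_orth=config.model.n_orth,
                alpha=config.screen.alpha, r_rule=config.screen.r_rule,
                vip_top=config.screen.vip_top, folds=config.model.folds,
                n_perm=config.model.n_perm, seed=seed + i)
        except (screen.ScreenError, chemo.ChemoError) as exc:
            raise PipelineError("model", f"comparison {day}: {exc}") from exc
        comparisons[res.label] = res
        cells[res.label] = res.stats
        (models_dir / f"{res.label}.json").write_text(json.dumps(res.summary, indent=2))
        res.stats.to_csv(models_dir / f"{res.label}_stats.csv")
        screen.build_volcano(res.stats).to_csv(volcano_dir / f"{res.label}.csv", index=False)
        manifest.models[res.label] = res.summary
        log.info("model %s: R2Y=%.3f Q2=%.3f, %d significant", res.label,
                 res.summary["r2y"], res.summary["q2"], int(res.stats["significant"].sum()))
    report = screen.build_report(
        cells, display_r_threshold=screen.critical_r(config.screen.alpha,
                                                     config.screen.report_r_df))
    report_dir = out / "report"
    report_dir.mkdir(exist_ok=True)
    report.to_csv(report_dir / "report.csv")
    (report_dir / "report.json").write_text(json.dumps(report.to_records(), indent=2))
    manifest.stages["screen"] = {"outputs": [str(report_dir / "report.csv"),
                                             str(report_dir / "report.json")]}
    return comparisons, cells, report


def _stage_enrich(config: RunConfig, cells, quantified, out: Path,
                  manifest: RunManifest) -> None:
    if not config.enrich.enabled:
        return
    hits = sorted({feat for df in cells.values()
                   for feat in df.index[df["significant"]]})
    background = list(quantified.values.columns)
    if config.enrich.pathways:
        pathways = enrich.read_pathways(config.enrich.pathways)
    else:
        pathways = enrich.load_demo_pathways()
    results = enrich.ora(hits, background, pathways) if hits else []
    path = out / "enrich.csv"
    enrich.results_frame(results).to_csv(path, index=False)
    manifest.stages["enrich"] = {"outputs": [str(path)], "n_hits": len(hits),
                                 "n_pathways_tested": len(results)}
    log.info("enrich: %d hits, %d pathways tested", len(hits), len(results))


def run(config: RunConfig) -> RunManifest:
    """Execute the pipeline for one fluid; returns the run manifest.

    Stage order: acquire (simulate or read spectra) -> preprocess
    (calibrate, bin, normalize, quantify) -> per-day OPLS-DA with
    validation -> three-criterion screen and masked report -> pathway ORA
    on the union of significant metabolites.  Identical config + seed
    reproduces identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest = RunManifest(config_hash=config.config_hash(), version=__version__)
    try:
        cohort, library = _stage_acquire(config, out, manifest)
        quantified = _stage_preprocess(config, cohort, library, out, manifest)
        comparisons, cells, report = _stage_model_screen(config, quantified, out, manifest)
        sig = sorted({feat for df in cells.values()
                      for feat in df.index[df["significant"]]})
        reported = report.significant_metabolites()
        manifest.counts = {
            "significant_metabolites": len(sig),
            "significant_names": sig,
            "reported_metabolites": len(reported),  # >=1 cell above the display |r|
            "per_comparison": {label: int(df["significant"].sum())
                               for label, df in cells.items()}}
        _stage_enrich(config, cells, quantified, out, manifest)
    except PipelineError as exc:
        manifest.status = f"FAILED: {exc}"
        manifest.to_json(out / "manifest.json")
        (out / "FAILED").write_text(str(exc))
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    manifest.to_json(out / "manifest.json")
    return manifest
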