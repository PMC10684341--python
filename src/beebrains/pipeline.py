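"""End-to-end runner: records -> occupancy classes -> comparative models.

The pipeline chains every stage of the analysis: filter occurrence records,
assign habitats, build the count matrix, score it against the fixed-margin
null model, fit the brain-body PGLS, estimate phylogenetic signal, and
regress the high/low occupancy class of each habitat on relative brain size
(and optionally on absolute log brain mass and log body size).  The report
doubles as a filter ledger: it records counts before and after every
filtering stage, every substream seed, and all fitted models, and is
byte-identical for identical config + seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allometry as allo
from . import models as cm
from . import occupancy as occ
from .phylo import PhyloTree, match_tips, phylo_covariance, read_newick
from .simulate import ScenarioBundle, ScenarioConfig, make_scenario, spawn_seeds

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "subset_by_region"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name in its message."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Everything needed to run (and exactly reproduce) one analysis."""

    # either a scenario ...
    scenario: ScenarioConfig | None = None
    # ... or paths to real inputs
    tree_path: str | None = None
    specimens_path: str | None = None
    records_path: str | None = None
    grid_path: str | None = None
    # filters
    min_year: int = 1990
    max_year: int = 2022
    min_decimals: int = 2
    min_records: int = 50
    # null model
    n_sim: int = 10_000
    high: float = 80.0
    low: float = 20.0
    ties: str = "strict"
    # models
    signal: bool = True
    predictors: tuple[str, ...] = ("relative", "log_brain", "log_body")
    prior_sd: float | None = 5.0
    signal_reference: str = "chisq1"
    # misc
    region: str | None = None
    exclude_species: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.low < self.high <= 100:
            raise ValueError("invalid percentile thresholds")
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        unknown = set(self.predictors) - {"relative", "log_brain", "log_body"}
        if unknown:
            raise ValueError(f"unknown predictors: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("scenario",)
        }
        d["predictors"] = list(self.predictors)
        d["exclude_species"] = list(self.exclude_species)
        d["scenario"] = self.scenario.to_dict() if self.scenario else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("scenario"):
            d["scenario"] = ScenarioConfig.from_dict(d["scenario"])
        if "predictors" in d and d["predictors"] is not None:
            d["predictors"] = tuple(d["predictors"])
        if "exclude_species" in d and d["exclude_species"] is not None:
            d["exclude_species"] = tuple(d["exclude_species"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(data)


@dataclass
class PipelineReport:
    """Machine-readable record of one pipeline run."""

    stage_counts: dict = field(default_factory=dict)
    occupancy_summary: dict = field(default_factory=dict)
    allometry: dict = field(default_factory=dict)
    signal: dict = field(default_factory=dict)
    logistic: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "stage_counts": self.stage_counts,
            "occupancy_summary": self.occupancy_summary,
            "allometry": self.allometry,
            "signal": self.signal,
            "logistic": self.logistic,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _load_bundle(config: PipelineConfig) -> ScenarioBundle:
    if config.scenario is not None:
        return make_scenario(config.scenario)
    missing = [
        name
        for name, p in (
            ("tree_path", config.tree_path),
            ("specimens_path", config.specimens_path),
            ("records_path", config.records_path),
            ("grid_path", config.grid_path),
        )
        if p is None
    ]
    if missing:
        raise PipelineError("inputs", f"missing inputs: {missing} (and no scenario)")
    tree = read_newick(Path(config.tree_path).read_text())
    specimens = pd.read_csv(config.specimens_path)
    records = occ.load_records(config.records_path)
    grid = occ.HabitatGrid.load(config.grid_path)
    return ScenarioBundle(tree=tree, specimens=specimens, records=records, grid=grid)


def subset_by_region(bundle: ScenarioBundle, region: str) -> ScenarioBundle:
    """Restrict a bundle to species collected in one region.

    Species whose region is ``both`` belong to every region.  The tree is
    pruned downstream by tip matching, so only tables are subset here.
    """
    if "region" not in bundle.specimens.columns:
        raise PipelineError("region", "specimen table has no region column")
    regions = set(bundle.specimens["region"].unique()) - {"both"}
    if region not in regions:
        raise PipelineError("region", f"region {region!r} not found (have {sorted(regions)})")
    keep = bundle.specimens["region"].isin([region, "both"])
    species = set(bundle.specimens.loc[keep, "species"])
    return ScenarioBundle(
        tree=bundle.tree,
        specimens=bundle.specimens.loc[keep].copy(),
        records=bundle.records[bundle.records["species"].isin(species)].copy(),
        grid=bundle.grid,
        truth=bundle.truth,
    )


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineReport:
    """Execute every stage and return (and optionally write) the report."""
    null_seed, = spawn_seeds(config.seed, 1)
    report = PipelineReport()
    report.provenance = {
        "config": config.to_dict(),
        "null_model_seed": null_seed,
        "package": "beebrains",
    }

    bundle = _load_bundle(config)
    if config.region is not None:
        bundle = subset_by_region(bundle, config.region)
    records = bundle.records
    if config.exclude_species:
        records = records[~records["species"].isin(config.exclude_species)]
    report.stage_counts["records_input"] = int(len(records))

    try:
        records = occ.filter_records(
            records,
            min_year=config.min_year,
            max_year=config.max_year,
            min_decimals=config.min_decimals,
        )
    except Exception as exc:
        raise PipelineError("filter", str(exc)) from exc
    report.stage_counts["records_after_filters"] = int(len(records))

    try:
        labelled, assign_report = occ.assign_habitat(records, bundle.grid)
    except Exception as exc:
        raise PipelineError("assign_habitat", str(exc)) from exc
    report.stage_counts["records_assigned"] = int(assign_report["n_assigned"])
    report.stage_counts["records_outside_grid"] = int(assign_report["n_outside"])

    matrix = occ.build_matrix(labelled)
    report.stage_counts["species_with_records"] = int(len(matrix))
    try:
        matrix = occ.apply_min_records(matrix, config.min_records)
    except Exception as exc:
        raise PipelineError("min_records", str(exc)) from exc
    report.stage_counts["species_after_min_records"] = int(len(matrix))

    # reconcile species across traits, records and tree
    try:
        traits = allo.species_means(bundle.specimens)
    except Exception as exc:
        raise PipelineError("species_means", str(exc)) from exc
    shared = sorted(set(matrix.index) & set(traits.index))
    try:
        tree, match_report = match_tips(bundle.tree, set(shared))
    except Exception as exc:
        raise PipelineError("match_tips", str(exc)) from exc
    species = [t for t in tree.tip_labels if t in set(shared)]
    matrix = matrix.loc[species]
    traits = traits.loc[species]
    report.stage_counts["species_analyzed"] = int(len(species))
    report.provenance["tip_match"] = {
        "tips_dropped": match_report.tips_dropped,
        "species_missing_from_tree": match_report.species_missing_from_tree,
    }

    try:
        result = occ.occupancy_percentiles(
            matrix,
            n_sim=config.n_sim,
            seed=null_seed,
            ties=config.ties,
            high=config.high,
            low=config.low,
        )
    except Exception as exc:
        raise PipelineError("null_model", str(exc)) from exc
    counts = result.class_counts()
    report.occupancy_summary = {
        hab: {k: int(v) for k, v in counts.loc[hab].items()} for hab in counts.index
    }

    V = phylo_covariance(tree)
    try:
        fit = allo.fit_pgls(traits, V)
    except Exception as exc:
        raise PipelineError("allometry", str(exc)) from exc
    report.allometry = fit.to_dict()
    predictors = {
        "relative": fit.residuals,
        "log_brain": traits["log_brain"],
        "log_body": traits["log_body"],
    }

    if config.signal:
        try:
            sig = cm.pagel_lambda_signal(
                fit.residuals,
                V,
                reference=config.signal_reference,
                seed=null_seed + 1,
            )
            report.signal["relative_brain_size"] = sig.to_dict()
            degree = result.matrix("percentile") / 100.0
            for hab in occ.HABITATS:
                trait = degree[hab].loc[species]
                if float(np.var(trait)) > 0:
                    shab = cm.pagel_lambda_signal(
                        trait,
                        V,
                        reference=config.signal_reference,
                        seed=null_seed + 2 + occ.HABITATS.index(hab),
                    )
                    report.signal[f"occupancy_{hab}"] = shab.to_dict()
        except Exception as exc:
            raise PipelineError("signal", str(exc)) from exc

    klass = result.matrix("klass")
    for hab in occ.HABITATS:
        report.logistic[hab] = {}
        kl = klass[hab].loc[species]
        mask = kl.isin(["high", "low"])
        y = (kl[mask] == "high").astype(float)
        if y.nunique() < 2:
            report.logistic[hab]["error"] = "single occupancy class; model skipped"
            continue
        used = list(y.index)
        Vsub = V.reorder(used)
        for name in config.predictors:
            x = predictors[name].loc[used]
            try:
                lfit = cm.phylo_logistic_fit(y, x, Vsub, prior_sd=config.prior_sd)
            except Exception as exc:
                raise PipelineError("logistic", f"{hab}/{name}: {exc}") from exc
            report.logistic[hab][name] = lfit.to_dict()

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(report.to_json() + "\n")
        result.to_csv(out_dir / "occupancy.csv")
        allo.relative_brain_size(fit).to_csv(out_dir / "relative_brain_size.csv")
    return report
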