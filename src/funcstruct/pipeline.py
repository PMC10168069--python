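"""One-call orchestration of the full analysis.

Order of stages: read (or simulate) -> prune + standardize traits -> filter
plots -> null ensemble -> SES -> soil predictor selection + log transform ->
mixed-model gradient tests -> reports. Every output carries the seed and a
hash of the configuration; a run log records each default that fired.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as fio
from .gradients import fit_gradient_model, log_transform_predictors, select_soil_variables
from .nullmodels import generate_null_ensemble
from .ses import compute_ses, filter_plots
from .simulate import PRESETS, make_fixture
from .traits import prune_correlated_traits, standardize_traits

log = logging.getLogger(__name__)

DEFAULT_TRAITS = ("LT", "PH", "LS", "LA", "SLA", "LDMC")


@dataclass
class RunConfig:
    """Configuration of one pipeline run; defaults match the study's choices
    (999 replicates, independent swap, plots with more than two species,
    traits LT/PH/LS/LA/SLA/LDMC)."""

    community: str | None = None
    traits_file: str | None = None
    soil: str | None = None
    site_map: str | None = None
    layout: str = "wide"
    preset: str | None = None  # alternative to the four paths above
    traits: tuple = DEFAULT_TRAITS
    prune_threshold: float = 0.70
    null_algorithm: str = "independent_swap"
    n_rep: int = 999
    seed: int = 42
    min_richness: int = 3
    abundance_weighted: bool = False
    predictors: tuple | None = None  # None -> automatic selection
    model_mode: str = "single"
    cor_threshold: float = 0.70
    vif_threshold: float = 5.0
    outdir: str = "funcstruct_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.traits, list):
            cfg.traits = tuple(cfg.traits)
        if isinstance(cfg.predictors, list):
            cfg.predictors = tuple(cfg.predictors)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _load_inputs(config: RunConfig):
    if config.preset:
        if config.preset not in PRESETS:
            raise ValueError(f"unknown preset {config.preset!r}")
        ds = make_fixture(config.preset, seed=config.seed if config.preset != "tiny" else None)
        return ds.community, ds.traits, ds.soil
    if not (config.community and config.traits_file and config.soil):
        raise ValueError("either a preset or community/traits_file/soil paths are required")
    return fio.read_dataset(
        config.community, config.traits_file, config.soil,
        site_map=config.site_map, layout=config.layout,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the result bundle and writes it to disk."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("funcstruct")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    results: dict = {"config": dataclasses.asdict(config), "config_hash": config.config_hash()}
    try:
        cm, tt, st = _load_inputs(config)
        report = fio.validate_dataset(cm, tt, st)
        results["validation"] = report.to_dict()
        if not report.is_ready:
            log.warning("dataset has alignment issues: %s", report.to_dict())

        available = [t for t in config.traits if t in tt.trait_names]
        if len(available) < len(config.traits):
            log.info("traits restricted to available set %s", available)
        tt_pruned = prune_correlated_traits(tt, threshold=config.prune_threshold)
        analysis_traits = [t for t in available if t in tt_pruned.trait_names]
        tt_std = standardize_traits(tt_pruned)
        log.info("analysis traits after pruning at |r|>%.2f: %s", config.prune_threshold, analysis_traits)

        cm_f = filter_plots(cm, min_richness=config.min_richness)
        tt_std = tt_std.subset(analysis_traits) if analysis_traits else tt_std
        tt_std = type(tt_std)(
            tt_std.values.loc[[s for s in tt_std.species_ids if s in set(cm_f.species_ids)]],
            tt_std.standardized, dict(tt_std.meta),
        )

        ensemble = generate_null_ensemble(
            cm_f, algorithm=config.null_algorithm, n_rep=config.n_rep, seed=config.seed
        )
        ses_table = compute_ses(
            cm_f, tt_std, ensemble, traits=analysis_traits,
            abundance_weighted=config.abundance_weighted,
        )
        results["ses"] = ses_table
        fio.write_table(ses_table, outdir / "ses.csv", seed=config.seed)

        st_plots = st.values.loc[[p for p in cm_f.plot_ids if p in set(st.plot_ids)]]
        st_f = type(st)(st_plots, dict(st.units))
        if config.predictors is None:
            selection = select_soil_variables(
                st_f, cor_threshold=config.cor_threshold, vif_threshold=config.vif_threshold
            )
            predictors = selection.selected
            results["selection"] = selection.to_dict()
            log.info("automatic predictor selection: %s", predictors)
        else:
            predictors = list(config.predictors)
            results["selection"] = {"selected": predictors, "audit": ["user-specified"]}
        (outdir / "selection.json").write_text(json.dumps(results["selection"], indent=2))

        loggable = [p for p in predictors if p != "pH"]
        st_log = log_transform_predictors(st_f, loggable) if loggable else st_f
        report_single = fit_gradient_model(ses_table, st_log, predictors, mode="single")
        report_multi = fit_gradient_model(ses_table, st_log, predictors, mode="multi")
        import pandas as pd

        model_report = pd.concat([report_single, report_multi], ignore_index=True)
        results["models"] = model_report
        fio.write_table(model_report, outdir / "model_report.csv", seed=config.seed)

        manifest = {
            "config": results["config"],
            "config_hash": results["config_hash"],
            "n_plots_analyzed": cm_f.n_plots,
            "n_species_analyzed": cm_f.n_species,
            "analysis_traits": analysis_traits,
            "predictors": list(predictors),
            "outputs": ["ses.csv", "model_report.csv", "selection.json", "run.log"],
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        results["manifest"] = manifest
        return results
    finally:
        root.removeHandler(handler)
        handler.close()
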