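"""End-to-end orchestration: one config, all stages, reproducible outputs.

Stage order mirrors the analysis workflow: validate the trial table,
group statistics on fixation durations and selection outcome, the four
standard SMART contrasts, the eight-variant diffusion fits with model
selection, and the parameter-level ANOVAs. Every run writes a manifest
listing its inputs, seeds and artifacts; rerunning with the same config
and seed reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitting import FitOptions, select_model, trim_outliers
from .inference import MissingCellError, cell_means, parameter_effects, rm_anova, wilcoxon_test
from .models import SaccadeDDM, SmartTimecourse
from .session import Session, read_trials, validate_session, write_trials
from .smart import STANDARD_CONTRASTS, SmartConfig
from .synth import SyntheticConfig, generate_session

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "input": None,  # path to a trial CSV; when null, simulate
    "generator": {},  # SyntheticConfig overrides
    "fitting": {},  # FitOptions overrides
    "trim": 0.0,  # outlier-trimming fraction before fitting
    "smart": {},  # SmartConfig overrides
    "contrasts": list(STANDARD_CONTRASTS),
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = {**DEFAULT_CONFIG, **user}
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def _config_digest(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_digest: str
    seed: int
    input_source: str
    artifacts: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)
    timing_s: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


class StageError(RuntimeError):
    def __init__(self, stage, original):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {original}")


def run_pipeline(config, out_dir) -> RunManifest:
    """Execute every stage and write all tables plus the run manifest."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = RunManifest(
        config_digest=_config_digest(cfg),
        seed=seed,
        input_source=cfg["input"] or "simulated",
        versions={"driftgaze": __version__},
    )

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, exc) from exc
        manifest.timing_s[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.1fs", name, manifest.timing_s[name])
        return result

    def _emit(key, path):
        manifest.artifacts[key] = str(path)
        return path

    # ---- input ----------------------------------------------------------
    def load():
        if cfg["input"]:
            return read_trials(cfg["input"])
        gen = SyntheticConfig(**{**cfg["generator"], "seed": seed})
        session = generate_session(gen)
        write_trials(session, _emit("trials", out / "trials.csv"))
        with open(_emit("generator_truth", out / "generator_truth.json"), "w") as fh:
            json.dump(
                {"config": session.metadata["config"],
                 "true_params": session.metadata["true_params"]},
                fh, indent=2,
            )
        return session

    session = _stage("load", load)

    # ---- validation ------------------------------------------------------
    def validate():
        report = validate_session(session)
        (_emit("validation", out / "validation.txt")).write_text(report.summary() + "\n")
        return report

    _stage("validate", validate)

    # ---- group statistics ------------------------------------------------
    def group_stats():
        results = {}
        for measure, design in [("fixation_duration", "2x2x2"), ("face_choice", "2x2")]:
            table = cell_means(session, measure, design)
            try:
                anova = rm_anova(table)
            except MissingCellError as err:
                logger.warning("%s ANOVA: excluding %s", measure, err.participants)
                kept = table.complete
                table = type(table)(values=kept, design=design, measure=measure)
                anova = rm_anova(table)
            anova.to_csv(_emit(f"anova_{measure}", out / f"anova_{measure}.csv"))
            results[measure] = anova
        choice = cell_means(session, "face_choice", "2x2").values
        wil = pd.DataFrame(
            {c[0]: wilcoxon_test(choice[c].dropna(), 0.5) for c in choice.columns}
        ).T
        wil.to_csv(_emit("choice_vs_chance", out / "choice_vs_chance.csv"))
        return results

    _stage("group_stats", group_stats)

    # ---- SMART time courses ----------------------------------------------
    def smart_stage():
        scfg = SmartConfig(**{**cfg["smart"], "seed": seed})
        rows = []
        for contrast in cfg["contrasts"]:
            res = SmartTimecourse(session, contrast, scfg).fit()
            top = res.strongest_cluster
            rows.append(
                {"contrast": contrast, "t_crit": res.t_crit,
                 "cluster_start_ms": top.start_ms if top else np.nan,
                 "cluster_end_ms": top.end_ms if top else np.nan,
                 "cluster_strength": top.strength if top else np.nan,
                 "p": top.p if top else np.nan,
                 "n_clusters": len(res.clusters)}
            )
            curves = pd.DataFrame({"time_ms": res.grid, "curve_a": res.curve_a,
                                   "ci_halfwidth": res.ci_halfwidth})
            if res.curve_b is not None:
                curves["curve_b"] = res.curve_b
            curves.to_csv(_emit(f"smart_{contrast}", out / f"smart_{contrast}.csv"), index=False)
        report = pd.DataFrame(rows).set_index("contrast")
        report.to_csv(_emit("smart_clusters", out / "smart_clusters.csv"))
        return report

    _stage("smart", smart_stage)

    # ---- diffusion fits and model selection ------------------------------
    def fits_stage():
        trials = session.trials
        if cfg["trim"]:
            trials, removed = trim_outliers(trials, float(cfg["trim"]))
            removed.to_csv(_emit("trimmed_trials", out / "trimmed_trials.csv"), index=False)
        opts = FitOptions(**{"seed": seed, **cfg["fitting"]})
        model = SaccadeDDM(Session(trials), options=opts)
        family = model.fit_family()
        weights = family.information_weights
        weights.to_csv(_emit("information_weights", out / "information_weights.csv"))
        winner, mean_w = select_model(weights)
        with open(_emit("model_selection", out / "model_selection.json"), "w") as fh:
            json.dump({"selected": winner.name, "k": winner.k,
                       "mean_weights": mean_w.to_dict()}, fh, indent=2)
        selected = family.results_for(winner)
        selected.params.to_csv(_emit("selected_params", out / "selected_params.csv"), index=False)
        return selected

    selected = _stage("fits", fits_stage)

    # ---- parameter-level inference ---------------------------------------
    def effects_stage():
        report = selected.parameter_effects()
        (_emit("parameter_effects", out / "parameter_effects.txt")).write_text(
            report.summary() + "\n"
        )
        report.condition_stats.to_csv(
            _emit("parameter_condition_stats", out / "parameter_condition_stats.csv")
        )
        return report

    _stage("effects", effects_stage)

    with open(_emit("manifest", out / "manifest.json"), "w") as fh:
        fh.write(manifest.to_json())
    return manifest
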