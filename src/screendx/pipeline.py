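"""End-to-end reproducible pipeline: simulate -> sample -> impute -> ipw ->
estimate -> roc -> report, driven by one flat config file.

Every run writes a manifest (config hash, seeds, output files, warnings) and
a single JSON report mirroring the structure of a two-phase accuracy study's
results: per-test accuracy estimates with bootstrap CIs, weighted
prevalences, the cut-point table and ROC-GLM covariate tests.  The report is
deterministic given (config, seed); timestamps live only in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .accuracy import TestDefinition, estimate_accuracy, prevalence_estimates
from .cohort import CohortConfig, generate_population
from .design import frame_totals, two_phase_sample
from .exceptions import PipelineError
from .io import OPTIONAL_NUMERIC_COLUMNS, write_cohort_csv
from .missing import apply_combined_weights, fit_response_model, pmm_impute
from .roc import compare_roc_groups, cutpoint_table, empirical_roc, fit_roc_glm

log = logging.getLogger("screendx")

DEFAULT_PIPELINE_CONFIG = {
    "seed": 20140075,
    "n_screen": 10000,
    "negative_schedule": [[0, 4], [5000, 6]],
    "donor_k": 5,
    "bootstrap_B": 200,
    "tests": ["either", "both", "help", "epds:13"],
    "diagnoses": ["depression", "any_disorder"],
    "prevalence_labels": ["depression", "anxiety", "any_disorder"],
    "cutoffs": list(range(9, 17)),
    "roc_covariates": ["age"],
    "t_grid": [0.02, 0.98, 0.02],
}


def load_pipeline_config(path) -> dict:
    """Flat key-value YAML; unknown keys rejected to catch typos."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    unknown = set(user) - set(DEFAULT_PIPELINE_CONFIG) - {"cohort"}
    if unknown:
        raise PipelineError(f"unknown config keys: {sorted(unknown)}")
    config = dict(DEFAULT_PIPELINE_CONFIG)
    config.update(user)
    return config


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _json_default(obj):
    import dataclasses
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute the whole synthetic-study pipeline; returns the manifest."""
    if not isinstance(config, dict):
        config = load_pipeline_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "config": config,
        "config_hash": config_hash(config),
        "seed": config["seed"],
        "started_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": [],
        "warnings": [],
    }
    seed = int(config["seed"])
    stage = "simulate"
    try:
        cohort_kwargs = dict(config.get("cohort") or {})
        cohort_kwargs["n_screen"] = int(config["n_screen"])
        cohort_cfg = CohortConfig(**cohort_kwargs)
        population = generate_population(cohort_cfg, seed)
        path = out / "cohort.csv"
        write_cohort_csv(population, path)
        manifest["outputs"].append(str(path))
        log.info("simulate: %d women generated", len(population))

        stage = "sample"
        schedule = [tuple(x) for x in config["negative_schedule"]]
        sampled, weights = two_phase_sample(population, schedule, seed + 1)
        frame = frame_totals(population)
        path = out / "sampled.csv"
        write_cohort_csv(sampled, path, extra_columns=OPTIONAL_NUMERIC_COLUMNS)
        manifest["outputs"].append(str(path))
        with open(out / "frame_totals.json", "w") as fh:
            json.dump({"frame": frame,
                       "weights": {h: {"frame_count": w.frame_count,
                                       "interviewed_count": w.interviewed_count,
                                       "weight": w.weight}
                                   for h, w in weights.items()}}, fh, indent=2)
        manifest["outputs"].append(str(out / "frame_totals.json"))
        interviewed = sampled[sampled["interviewed"] == 1].reset_index(drop=True)
        log.info("sample: %d interviewed (weights %s)", len(interviewed),
                 {h: round(w.weight, 4) for h, w in weights.items()})

        stage = "impute"
        n_item_missing = int(interviewed[[c for c in interviewed.columns
                                          if c.startswith("item_")]]
                             .isna().any(axis=1).sum())
        imputation = pmm_impute(interviewed, donor_k=int(config["donor_k"]),
                                seed=seed + 2)
        interviewed = imputation.completed
        if n_item_missing == 0:
            manifest["warnings"].append("impute: no missing items; stage was a no-op")
        log.info("impute: %d cells imputed, %d records excluded (>30%% missing)",
                 int(imputation.imputed_mask.to_numpy().sum()),
                 len(imputation.excluded_ids))

        stage = "ipw"
        ipw_models = {}
        for label in config["diagnoses"]:
            model = fit_response_model(interviewed, label)
            interviewed = apply_combined_weights(interviewed, model)
            interviewed[f"analysis_weight_{label}"] = interviewed["analysis_weight"]
            ipw_models[label] = model.summary_dict()
            if interviewed.attrs.get("n_weight_capped", 0):
                manifest["warnings"].append(
                    f"ipw[{label}]: {interviewed.attrs['n_weight_capped']} "
                    "weights capped at the probability floor")
        all_observed = all(
            (interviewed[f"module_observed_{lab if lab != 'any_disorder' else 'any'}"]
             == 1).all() for lab in config["diagnoses"])
        if all_observed:
            manifest["warnings"].append("ipw: no module missingness; stage was a no-op")
        with open(out / "ipw_models.json", "w") as fh:
            json.dump(ipw_models, fh, indent=2, default=_json_default)
        manifest["outputs"].append(str(out / "ipw_models.json"))

        stage = "estimate"
        B = int(config["bootstrap_B"])
        estimates = {}
        for label in config["diagnoses"]:
            wcol = f"analysis_weight_{label}"
            per_test = {}
            for i, spec in enumerate(config["tests"]):
                test = TestDefinition.parse(spec)
                table, est = estimate_accuracy(
                    interviewed, test, label, weight_col=wcol,
                    B=B, seed=seed + 10 + i)
                per_test[spec] = {
                    "raw_cells": {"tp": table.raw_tp, "fp": table.raw_fp,
                                  "fn": table.raw_fn, "tn": table.raw_tn},
                    "weighted_cells": {"tp": table.tp, "fp": table.fp,
                                       "fn": table.fn, "tn": table.tn},
                    "n_excluded": table.n_excluded,
                    "estimates": est.as_dict(),
                }
            estimates[label] = per_test
        prevalences = prevalence_estimates(
            interviewed, config["prevalence_labels"],
            weight_col="design_weight", B=B, seed=seed + 20)
        log.info("estimate: %d tests x %d diagnoses",
                 len(config["tests"]), len(config["diagnoses"]))

        stage = "roc"
        ref_label = config["diagnoses"][0]
        wcol = f"analysis_weight_{ref_label}"
        curve = empirical_roc(interviewed, "total_score", ref_label, wcol)
        cuts = cutpoint_table(interviewed, "total_score", ref_label, wcol,
                              cutoffs=list(config["cutoffs"]))
        lo, hi, step = config["t_grid"]
        t_grid = np.round(np.arange(lo, hi + step / 2, step), 6)
        fit = fit_roc_glm(interviewed, "total_score", ref_label,
                          covariates=list(config["roc_covariates"]),
                          weight_col=wcol, t_grid=t_grid)
        covariate_tests = {}
        for group in fit.groups:
            chi2, dof, p = compare_roc_groups(fit, group)
            covariate_tests[group] = {"chi2": chi2, "df": dof, "p": p}
        manifest["warnings"].extend(fit.warnings)
        curve_csv = out / "roc_curve.csv"
        with open(curve_csv, "w") as fh:
            fh.write("t,roc_t\n")
            for t, r in zip(curve.fpr, curve.tpr):
                fh.write(f"{t:.6f},{r:.6f}\n")
        manifest["outputs"].append(str(curve_csv))

        stage = "report"
        report = {
            "config_hash": manifest["config_hash"],
            "seed": seed,
            "n_screened": len(population),
            "n_interviewed": len(interviewed),
            "design_weights": {h: w.weight for h, w in weights.items()},
            "prevalence": prevalences.to_dict(orient="records"),
            "accuracy": estimates,
            "epds_auc_weighted": curve.auc,
            "cutpoint_table": cuts.to_dict(orient="records"),
            "roc_glm": {
                "alpha0": fit.alpha0, "alpha1": fit.alpha1,
                "beta": fit.beta.to_dict(),
                "auc_at_reference": fit.auc(),
                "covariate_tests": covariate_tests,
            },
        }
        report_path = out / "report.json"
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        manifest["outputs"].append(str(report_path))
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest["finished_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
    return manifest
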