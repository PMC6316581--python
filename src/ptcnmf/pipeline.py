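"""End-to-end orchestration: preprocess -> NMF survey/fit -> classification
-> immune profiling -> clinical association, with a reproducibility
manifest.

Each stage reads its inputs from disk and writes plain CSV/TSV outputs into
the configured output directory, so any stage can be re-run from the
on-disk outputs of earlier stages. A single global seed is expanded into
per-stage seeds by fixed offsets (survey: +0, final fit: +100000), and the
manifest records the config, seeds, package version and SHA-256 checksums
of every written file; identical manifests imply byte-identical outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import annotate_signatures, cluster_samples, label_clusters
from .clinical import build_table2, cox_fit, km_estimate, logrank_test
from .immune import (cluster_feature_summary, cyt_score,
                     feature_signature_correlation, signature_score)
from .nmf import (MetageneActivity, MetageneBasis, nmf_factorize, rank_survey,
                  select_rank)
from .readwrite import (log_transform, read_expression_tsv, read_gmt,
                        select_variable_genes)

logger = logging.getLogger(__name__)

STAGES = ("nmf", "classify", "immune", "assoc")

_SURVEY_SEED_OFFSET = 0
_FIT_SEED_OFFSET = 100000

DEFAULT_CONFIG = {
    "paths": {
        "expression": None,
        "clinical": None,
        "features": None,
        "gmt": None,
        "outdir": "ptcnmf_out",
    },
    "seed": None,
    "stages": list(STAGES),
    "nmf": {
        "ranks": [2, 3, 4, 5, 6],
        "rank": None,            # fixed rank; None = select from the survey
        "runs": 30,
        "max_iter": 500,
        "tol": 1e-5,
        "log_transform": True,
        "pseudocount": 1.0,
        "n_variable_genes": 5000,
        "drop_threshold": 0.01,
    },
    "classify": {
        "linkage": "ward",
        "min_overlap_frac": 0.5,
        "min_genes": 200,
        "projection_mode": "pinv",
    },
    "report": {
        "alpha": 0.05,
        "rounding": 2,
    },
}


class ConfigValidationError(ValueError):
    """Raised for unknown keys, bad types or missing required settings."""


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigValidationError(f"unknown config key {here!r}")
        if isinstance(defaults[key], dict) and defaults[key]:
            if not isinstance(value, dict):
                raise ConfigValidationError(f"{here!r} must be a mapping")
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


def validate_config(source) -> dict:
    """Normalise a YAML/JSON config file (or dict) against the schema.

    Unknown keys are rejected by name; defaults are filled in; the seed is
    mandatory. Returns the normalised config dict.
    """
    if isinstance(source, dict):
        user = source
    else:
        text = Path(source).read_text()
        user = yaml.safe_load(text)  # YAML is a superset of JSON
        if user is None:
            user = {}
    if not isinstance(user, dict):
        raise ConfigValidationError("config root must be a mapping")
    cfg = _merge(DEFAULT_CONFIG, user)
    if cfg["seed"] is None:
        raise ConfigValidationError("a seed is mandatory")
    cfg["seed"] = int(cfg["seed"])
    unknown = set(cfg["stages"]) - set(STAGES)
    if unknown:
        raise ConfigValidationError(f"unknown stage(s): {sorted(unknown)}")
    if "assoc" in cfg["stages"] and not cfg["paths"]["clinical"]:
        raise ConfigValidationError("the assoc stage requires paths.clinical")
    if "classify" in cfg["stages"] and not cfg["paths"]["clinical"]:
        raise ConfigValidationError("the classify stage requires paths.clinical "
                                    "(driver classes)")
    if not cfg["paths"]["expression"]:
        raise ConfigValidationError("paths.expression is required")
    logger.info("normalized config: %s", json.dumps(cfg, default=str))
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict) -> dict:
    """Execute the configured stages and write a reproducibility manifest.

    Returns a dict of in-memory stage results keyed by stage name. Any
    stage failure halts the run with the stage name; outputs written by
    earlier stages are preserved.
    """
    cfg = validate_config(config)
    outdir = Path(cfg["paths"]["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    written: list[Path] = []
    results: dict = {}

    stage = "preprocess"
    try:
        E = read_expression_tsv(cfg["paths"]["expression"])
        prep = E
        if cfg["nmf"]["log_transform"]:
            prep = log_transform(prep, cfg["nmf"]["pseudocount"])
        nvar = cfg["nmf"]["n_variable_genes"]
        if nvar and nvar < prep.n_genes:
            prep = select_variable_genes(prep, nvar)
        results["preprocess"] = prep

        clinical = None
        if cfg["paths"]["clinical"]:
            clinical = pd.read_csv(cfg["paths"]["clinical"], index_col=0)

        basis = activity = None
        if "nmf" in cfg["stages"]:
            stage = "nmf"
            n = cfg["nmf"]
            ranks = [k for k in (n["ranks"] or [])
                     if k < min(prep.n_genes, prep.n_samples)]
            if ranks:
                survey = rank_survey(prep, ranks, n_runs=n["runs"],
                                     base_seed=seed + _SURVEY_SEED_OFFSET,
                                     max_iter=n["max_iter"], tol=n["tol"])
                survey.to_frame().to_csv(outdir / "survey.csv", index=False)
                written.append(outdir / "survey.csv")
                results["survey"] = survey
            if n["rank"] is not None:
                rank = int(n["rank"])
            elif ranks:
                rank = select_rank(survey, n["drop_threshold"])
            else:
                raise ValueError("nmf.rank must be set when no ranks are surveyed")
            basis, activity = nmf_factorize(prep, rank,
                                            seed=seed + _FIT_SEED_OFFSET,
                                            max_iter=2 * n["max_iter"],
                                            tol=n["tol"] / 10)
            basis.to_frame().to_csv(outdir / "W.tsv", sep="\t")
            activity.to_frame().to_csv(outdir / "H.tsv", sep="\t")
            written += [outdir / "W.tsv", outdir / "H.tsv"]
            results["basis"], results["activity"] = basis, activity

        assignment = None
        if "classify" in cfg["stages"]:
            stage = "classify"
            if activity is None:
                basis, activity = _load_factors(outdir)
            marker = cyt_score(E)
            annotation = annotate_signatures(activity, clinical["driver_class"], marker)
            raw = cluster_samples(activity, 4, method=cfg["classify"]["linkage"])
            assignment = label_clusters(raw, annotation, activity)
            labels = assignment.to_frame()
            role_levels = activity.to_frame()
            for role in ("RAS", "Immune", "BRAF"):
                labels[f"sig_{role}"] = role_levels.loc[
                    annotation.signature_for(role)].values
            labels.to_csv(outdir / "labels.csv")
            written.append(outdir / "labels.csv")
            results["annotation"], results["assignment"] = annotation, assignment

        if "immune" in cfg["stages"]:
            stage = "immune"
            feats = pd.DataFrame(index=E.sample_ids)
            feats["cyt_score"] = cyt_score(E)
            if cfg["paths"]["gmt"]:
                sets = read_gmt(cfg["paths"]["gmt"])
                logE = log_transform(E, cfg["nmf"]["pseudocount"])
                for name, genes in sets.sets.items():
                    feats[f"score_{name}"] = signature_score(logE, genes, name)
            if cfg["paths"]["features"]:
                external = pd.read_csv(cfg["paths"]["features"], index_col=0)
                feats = feats.join(external, how="left")
            feats.to_csv(outdir / "features.csv")
            written.append(outdir / "features.csv")
            if activity is not None:
                cors = feature_signature_correlation(activity, feats)
                cors.to_csv(outdir / "correlations.csv")
                written.append(outdir / "correlations.csv")
            if assignment is not None:
                summary = cluster_feature_summary(feats, assignment,
                                                 alpha=cfg["report"]["alpha"])
                summary.to_csv(outdir / "cluster_feature_summary.csv")
                written.append(outdir / "cluster_feature_summary.csv")
            results["features"] = feats

        if "assoc" in cfg["stages"]:
            stage = "assoc"
            clin = clinical.copy()
            if assignment is not None:
                clin["cluster"] = assignment.to_frame()["cluster"]
            table2 = build_table2(clin, alpha=cfg["report"]["alpha"])
            table2["univariate"].round(6).to_csv(outdir / "table2.csv")
            written.append(outdir / "table2.csv")
            results["table2"] = table2
            if {"followup_time", "event"} <= set(clin.columns):
                curves = km_estimate(clin["followup_time"], clin["event"],
                                     clin["cluster"])
                km = pd.concat({g: df for g, df in curves.items()},
                               names=["group", "row"])
                km.to_csv(outdir / "km_curves.csv")
                written.append(outdir / "km_curves.csv")
                chi2, dfree, p = logrank_test(clin["followup_time"],
                                              clin["event"], clin["cluster"])
                results["logrank"] = {"chi2": chi2, "df": dfree, "p": p}
                nmf3 = (clin["cluster"] == "NMF3").astype(int).to_frame("nmf3")
                results["cox_nmf3"] = cox_fit(clin["followup_time"],
                                              clin["event"], nmf3)
                results["km_curves"] = curves
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "config": cfg,
        "seed": seed,
        "stage_seeds": {"survey": seed + _SURVEY_SEED_OFFSET,
                        "fit": seed + _FIT_SEED_OFFSET},
        "outputs": {str(p.name): _sha256(p) for p in written},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str))
    results["manifest"] = manifest
    return results


def _load_factors(outdir: Path) -> tuple[MetageneBasis, MetageneActivity]:
    """Reload W/H written by a previous nmf stage run."""
    Wf = pd.read_csv(outdir / "W.tsv", sep="\t", index_col=0)
    Hf = pd.read_csv(outdir / "H.tsv", sep="\t", index_col=0)
    basis = MetageneBasis(Wf.index.tolist(), Wf.to_numpy(),
                          signature_names=Wf.columns.tolist())
    activity = MetageneActivity(Hf.columns.tolist(), Hf.to_numpy(),
                                signature_names=Hf.index.tolist())
    return basis, activity
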