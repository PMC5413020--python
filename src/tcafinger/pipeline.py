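"""End-to-end orchestration: simulate -> pretreat -> statistics ->
latent models -> annotation -> report, with a machine-readable manifest.

``RunConfig`` collects every stage parameter with its documented default
and round-trips losslessly through YAML.  ``run_pipeline`` executes the
stages in order on either a simulated cohort or feature/metadata files,
writes all artifacts into an output directory, and records counts, seeds
and parameter values in ``manifest.json``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import fingerprint_report, match_features, write_report
from .chem import load_adduct_rules, load_metabolite_library
from .multivariate import (
    choose_orthogonal_components,
    fit_oplsda,
    fit_pca,
    q2_crossval,
    rank_features,
    scale_matrix,
)
from .preprocess import FeatureTable, pretreat
from .simulate import CohortDesign, GroundTruth, generate_cohort, write_ground_truth
from .univariate import differential_analysis

__all__ = ["RunConfig", "run_pipeline", "simulate_to_files"]

log = logging.getLogger("tcafinger")


@dataclass
class RunConfig:
    """All tunable pipeline parameters with their defaults."""

    # inputs (None -> simulate a default cohort)
    features_path: Optional[str] = None
    samples_path: Optional[str] = None
    library_path: Optional[str] = None
    rules_path: Optional[str] = None
    # simulation
    seed: int = 0
    n_cases: int = 8
    n_controls: int = 30
    n_noise_features: int = 1000
    intensity_cv: float = 0.2
    missing_rate: float = 0.1
    mass_error_sd: float = 0.0005
    # pretreatment
    missing_threshold: float = 0.75
    # univariate
    p_cut: float = 0.05
    fc_cut: float = 1.5
    # multivariate
    scaling_mode: str = "uv"
    log_transform: bool = True
    # latent models are fitted on the matrix of selected differential
    # features (the pipeline's "final data matrix"); set False to use all
    # pretreated features
    multivariate_on_selected: bool = True
    pca_components: int = 16
    oplsda_orthogonal: int = -1  # -1 = choose by Q2-improvement rule
    cv_folds: int = 7
    # annotation
    tolerance: float = 0.003
    tolerance_mode: str = "da"
    rt_window: Optional[float] = None

    def to_yaml(self, path: str) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config field(s): {sorted(bad)}")
        return cls(**raw)


def _design_from_config(config: RunConfig) -> CohortDesign:
    kwargs: Dict[str, Any] = dict(
        n_cases=config.n_cases,
        n_controls=config.n_controls,
        n_noise_features=config.n_noise_features,
        intensity_cv=config.intensity_cv,
        missing_rate=config.missing_rate,
        mass_error_sd=config.mass_error_sd,
        seed=config.seed,
    )
    if config.n_cases != 8:
        kwargs["family_sizes"] = (config.n_cases,)
    return CohortDesign(**kwargs)


def simulate_to_files(config: RunConfig, out_dir: str, force: bool = False) -> Dict[str, str]:
    """Simulate a cohort and write the feature table, metadata and truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": str(out / "features.tsv"),
        "samples": str(out / "samples.tsv"),
        "ground_truth": str(out / "ground_truth.tsv"),
    }
    existing = [p for p in paths.values() if Path(p).exists()]
    if existing and not force:
        raise FileExistsError(
            f"refusing to overwrite {existing[0]} (use force=True / --force)"
        )
    design = _design_from_config(config)
    table, truth = generate_cohort(design)
    table.write(paths["features"], paths["samples"])
    write_ground_truth(truth, paths["ground_truth"])
    log.info(
        "simulated cohort: %d cases + %d controls, %d features",
        design.n_cases, design.n_controls, table.n_features,
    )
    return paths


def _load_input(config: RunConfig) -> Tuple[FeatureTable, Optional[pd.DataFrame]]:
    if config.features_path is None:
        design = _design_from_config(config)
        table, truth = generate_cohort(design)
        return table, truth.features
    if config.samples_path is None:
        raise ValueError("features_path given without samples_path")
    for p in (config.features_path, config.samples_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    return FeatureTable.read(config.features_path, config.samples_path), None


def run_pipeline(config: RunConfig, out_dir: str) -> Dict[str, Any]:
    """Execute the full pipeline; returns the manifest dictionary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, Any] = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
    }

    table, truth = _load_input(config)
    if truth is not None:
        write_ground_truth(
            GroundTruth(features=truth, samples=table.samples.copy()),
            str(out / "ground_truth.tsv"),
        )
    manifest["stages"]["input"] = {
        "n_features": table.n_features,
        "n_samples": table.n_samples,
        "n_cases": int((table.samples["class"] == "case").sum()),
        "n_controls": int((table.samples["class"] == "control").sum()),
    }

    pre = pretreat(table, config.missing_threshold)
    pre.write(str(out / "preprocessed.tsv"), str(out / "samples.tsv"))
    manifest["stages"]["pretreat"] = {
        "n_features_in": table.n_features,
        "n_features_out": pre.n_features,
        "n_removed": table.n_features - pre.n_features,
        "missing_threshold": config.missing_threshold,
    }

    results = differential_analysis(pre, p_cut=config.p_cut, fc_cut=config.fc_cut)
    results.to_csv(out / "differential.tsv", sep="\t", index_label="feature_id")
    prior = results.attrs["prior"]
    manifest["stages"]["univariate"] = {
        "n_features": len(results),
        "n_selected": int(results["selected"].sum()),
        "prior_s2": prior.s2_prior,
        "prior_df": prior.df_prior if np.isfinite(prior.df_prior) else "inf",
        "p_cut": config.p_cut,
        "fc_cut": config.fc_cut,
    }

    # latent models on (optionally log2) scaled intensities of the final
    # data matrix: the selected differential features when enough exist
    mv_index = pre.features.index
    if config.multivariate_on_selected and int(results["selected"].sum()) >= 3:
        mv_index = results.index[results["selected"]]
    mv_features = pd.Index(mv_index)
    X = pre.intensities.loc[mv_features].to_numpy(float).T  # samples x features
    if config.log_transform:
        X = np.log2(X)
    Xs, _ = scale_matrix(X, mode=config.scaling_mode)
    y = pre.samples["class"].to_numpy()

    n_comp = min(config.pca_components, Xs.shape[0] - 1, Xs.shape[1])
    pca = fit_pca(Xs, n_comp)
    pca_q2 = q2_crossval(
        Xs, kind="pca", n_components=n_comp, folds=config.cv_folds, seed=config.seed
    )
    n_orth = (
        choose_orthogonal_components(
            Xs, y, folds=config.cv_folds, seed=config.seed
        )
        if config.oplsda_orthogonal < 0
        else config.oplsda_orthogonal
    )
    opls = fit_oplsda(Xs, y, n_orthogonal=n_orth)
    opls_q2 = q2_crossval(
        Xs, kind="oplsda", y=y, n_orthogonal=n_orth,
        folds=config.cv_folds, seed=config.seed,
    )

    scores = pd.DataFrame(
        opls.scores,
        index=pre.samples.index,
        columns=["predictive"] + [f"orthogonal_{k + 1}" for k in range(n_orth)],
    )
    scores.insert(0, "class", pre.samples["class"])
    scores.to_csv(out / "oplsda_scores.tsv", sep="\t", index_label="sample_id")
    pd.DataFrame(
        pca.scores, index=pre.samples.index,
        columns=[f"PC{k + 1}" for k in range(n_comp)],
    ).to_csv(out / "pca_scores.tsv", sep="\t", index_label="sample_id")
    pd.DataFrame(
        opls.loadings, index=mv_features, columns=scores.columns[1:],
    ).to_csv(out / "oplsda_loadings.tsv", sep="\t", index_label="feature_id")
    ranking = rank_features(opls, list(mv_features))
    ranking.to_csv(out / "feature_ranking.tsv", sep="\t")
    metrics = {
        "n_features_matrix": int(len(mv_features)),
        "pca": {"R2X_cum": pca.r2x_cum, "Q2_cum": pca_q2, "components": n_comp},
        "oplsda": {
            "R2X_cum": opls.r2x_cum,
            "R2Y_cum": opls.r2y_cum,
            "Q2_cum": opls_q2,
            "orthogonal_components": n_orth,
        },
    }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    manifest["stages"]["multivariate"] = metrics

    library = load_metabolite_library(config.library_path)
    rules = load_adduct_rules(config.rules_path)
    annotations = match_features(
        pre.features,
        library,
        rules,
        tolerance=config.tolerance,
        tolerance_mode=config.tolerance_mode,
        rt_window=config.rt_window,
        fold_changes=results["fold_change"],
    )
    report = fingerprint_report(annotations)
    write_report(report, str(out / "annotation.tsv"))
    manifest["stages"]["annotate"] = {
        "n_metabolites_matched": int(
            sum(1 for a in annotations if a.forms)
        ),
        "n_feature_form_matches": int(len(report)),
        "n_ambiguous": int(sum(a.ambiguous for a in annotations)),
        "tolerance": config.tolerance,
    }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    log.info("pipeline complete: artifacts in %s", out)
    return manifest
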