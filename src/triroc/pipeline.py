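"""End-to-end study pipeline.

Runs the full evaluation on a cohort (simulated or read from CSV):
exclusion of non-randomly incomplete samples, reference-marker multiple
imputation, the descriptive/univariate battery, the Kendall/Hochberg
correlation matrix, Yeo-Johnson + correlation PCA, per-feature VUS with
bootstrap CIs, the four panel predictors (reference marker alone,
PC-based averaged model, concentration-based averaged model,
CAR-score model), and paired bootstrap non-inferiority/superiority
testing of each panel against the reference marker.  Every artifact is
written as CSV/JSON together with a manifest that suffices to re-run
the pipeline bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortConfig, CohortTable, generate_cohort
from .errors import ComputationError, ValidationError
from .noninferiority import delta_vus_test, forest_data
from .panels import (
    CandidateSet,
    DEFAULT_PSEUDO_RESPONSE,
    bma_mlogit,
    car_fit,
    score_samples,
)
from .preprocessing import (
    exclude_nonrandom_missing,
    impute_reference_marker,
    pca_transform,
)
from .stats import (
    gender_binomial_test,
    kendall_hochberg_matrix,
    pairwise_battery,
)
from .vus import OrderedMarkerTriple, vus_bootstrap_ci

logger = logging.getLogger(__name__)

PREDICTOR_NAMES = ("reference", "PCA", "AA", "CAR")


@dataclass
class PipelineConfig:
    """Settings of one pipeline run.

    Exactly one of ``input_path`` / ``simulate`` must be set.
    """

    simulate: CohortConfig | None = None
    input_path: str | None = None
    class_order: tuple[str, str, str] = ("H", "P", "C")
    refmarker: str = "refmarker"
    max_missing_features: int = 0
    vus_B: int = 2000
    ci_level: float = 0.95
    tie_rule: str = "partial"
    max_subset_size: int = 2
    occam_ratio: float = 20.0
    pseudo_response: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PSEUDO_RESPONSE)
    )
    car_k: int = 2
    delta: float = 0.05
    B_outer: int = 1000
    B_inner: int = 1000
    ci_method: str = "percentile"
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        if (self.simulate is None) == (self.input_path is None):
            raise ValidationError(
                "exactly one of simulate/input_path must be given"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data.get("simulate") is not None:
            sim = data["simulate"]
            if "n_per_class" in sim:
                sim["n_per_class"] = tuple(sim["n_per_class"])
            if "class_order" in sim:
                sim["class_order"] = tuple(sim["class_order"])
            if sim.get("refmarker_params") is not None:
                sim["refmarker_params"] = np.asarray(
                    sim["refmarker_params"], float
                )
            if sim.get("class_shifts") is not None:
                sim["class_shifts"] = np.asarray(sim["class_shifts"], float)
            data["simulate"] = CohortConfig(**sim)
        if "class_order" in data:
            data["class_order"] = tuple(data["class_order"])
        return cls(**data)


def _stage(name: str):
    """Wrap a pipeline stage so failures report the stage name."""
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (ValidationError, ComputationError):
                raise
            except Exception as exc:
                raise ComputationError(
                    f"stage {name!r} failed: {exc}"
                ) from exc
        return wrapped
    return deco


def _descriptives(table: CohortTable) -> pd.DataFrame:
    """Median (2.5-97.5 percentile) per class for every quantitative
    variable, plus gender counts and binomial P where available."""
    rows = []
    variables = table.metabolites + [table.refmarker]
    for var in variables:
        row = {"variable": var}
        for c in table.class_order:
            vals = table.data.loc[table.classes == c, var].dropna()
            med = vals.median()
            lo, hi = vals.quantile([0.025, 0.975])
            row[c] = f"{med:.1f} ({lo:.1f}-{hi:.1f})"
        rows.append(row)
    if "gender" in table.data.columns:
        row = {"variable": "gender (m/f)"}
        for c in table.class_order:
            g = table.data.loc[table.classes == c, "gender"]
            m, f = int((g == "m").sum()), int((g == "f").sum())
            p = gender_binomial_test((m, f))
            row[c] = f"{m}/{f} (P={p:.4f})"
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the artifact dictionary.

    When ``config.outdir`` is set, artifacts are also written there as
    CSV/JSON along with ``manifest.json``.
    """
    config.validate()
    seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2**31)

    # --- cohort ---------------------------------------------------------
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=int(seeds[0]))
        table = _stage("simulate")(generate_cohort)(sim)
    else:
        table = _stage("ingest")(CohortTable.from_csv)(
            config.input_path,
            class_order=config.class_order,
            refmarker=config.refmarker,
        )

    # --- exclusion & imputation ----------------------------------------
    table = _stage("exclude")(exclude_nonrandom_missing)(
        table, config.max_missing_features
    )
    imputation = _stage("impute")(impute_reference_marker)(
        table, seed=int(seeds[1])
    )
    table = imputation.table

    # --- univariate battery & correlations ------------------------------
    descriptives = _stage("descriptives")(_descriptives)(table)
    battery = _stage("pairwise")(pairwise_battery)(table)
    correlations = _stage("correlation")(kendall_hochberg_matrix)(table)

    # --- transforms & PCA ------------------------------------------------
    pca = _stage("pca")(pca_transform)(table)

    # --- per-feature VUS table -------------------------------------------
    @_stage("vus_features")
    def _vus_table() -> pd.DataFrame:
        rows = []
        for j, var in enumerate(table.metabolites + [table.refmarker]):
            triple = OrderedMarkerTriple(
                *table.marker_values(var), class_order=table.class_order
            )
            res = vus_bootstrap_ci(
                triple,
                B=config.vus_B,
                ci_level=config.ci_level,
                seed=int((seeds[2] + j) % (2**31)),
                tie_rule=config.tie_rule,
            )
            rows.append(
                {
                    "compound": var,
                    "VUS": res.vus,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                }
            )
        out = pd.DataFrame(rows).sort_values(
            "VUS", ascending=False, ignore_index=True
        )
        out.loc[len(out)] = {
            "compound": "Random",
            "VUS": 1.0 / 6.0,
            "ci_low": np.nan,
            "ci_high": np.nan,
        }
        return out

    vus_features = _vus_table()

    # --- panel models -----------------------------------------------------
    @_stage("models")
    def _models():
        y = table.classes.to_numpy()
        ref = table.data[table.refmarker].to_numpy(float)
        ref_frame = pd.DataFrame({table.refmarker: ref})

        pc_frame = pca.scores.reset_index(drop=True)
        pca_candidates = CandidateSet(
            X=pd.concat([ref_frame, pc_frame], axis=1),
            y=y,
            class_order=table.class_order,
            forced_in=[table.refmarker],
        )
        pca_model = bma_mlogit(
            pca_candidates,
            max_subset_size=config.max_subset_size,
            occam_ratio=config.occam_ratio,
        )

        conc_frame = table.data[table.metabolites].reset_index(drop=True)
        aa_candidates = CandidateSet(
            X=pd.concat([ref_frame, conc_frame], axis=1),
            y=y,
            class_order=table.class_order,
            forced_in=[table.refmarker],
        )
        aa_model = bma_mlogit(
            aa_candidates,
            max_subset_size=config.max_subset_size,
            occam_ratio=config.occam_ratio,
        )

        pseudo = {
            label: config.pseudo_response.get(label)
            for label in table.class_order
        }
        if any(v is None for v in pseudo.values()):
            pseudo = None
        car_model = car_fit(
            aa_candidates, pseudo_response=pseudo, k=config.car_k
        )

        scores = {
            "reference": ref,
            "PCA": score_samples(
                pca_model, pca_candidates.X
            ).scores,
            "AA": score_samples(aa_model, aa_candidates.X).scores,
            "CAR": score_samples(car_model, aa_candidates.X).scores,
        }
        return pca_model, aa_model, car_model, scores

    pca_model, aa_model, car_model, predictor_scores = _models()

    # --- predictor VUS ----------------------------------------------------
    @_stage("vus_predictors")
    def _predictor_vus() -> pd.DataFrame:
        rows = []
        for j, name in enumerate(PREDICTOR_NAMES):
            triple = OrderedMarkerTriple.from_labels(
                predictor_scores[name],
                table.classes.to_numpy(),
                class_order=table.class_order,
            )
            res = vus_bootstrap_ci(
                triple,
                B=config.vus_B,
                ci_level=config.ci_level,
                seed=int((seeds[3] + j) % (2**31)),
                tie_rule=config.tie_rule,
            )
            rows.append(
                {
                    "predictor": name,
                    "VUS": res.vus,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                }
            )
        return pd.DataFrame(rows)

    vus_predictors = _predictor_vus()

    # --- non-inferiority --------------------------------------------------
    @_stage("noninferiority")
    def _decisions():
        decisions = []
        labels = []
        for j, name in enumerate(PREDICTOR_NAMES[1:]):
            decisions.append(
                delta_vus_test(
                    predictor_scores[name],
                    predictor_scores["reference"],
                    table.classes.to_numpy(),
                    class_order=table.class_order,
                    delta=config.delta,
                    B_outer=config.B_outer,
                    B_inner=config.B_inner,
                    ci_method=config.ci_method,
                    tie_rule=config.tie_rule,
                    seed=int((seeds[4] + j) % (2**31)),
                )
            )
            labels.append(name)
        return forest_data(decisions, labels), decisions

    forest, decisions = _decisions()

    artifacts = {
        "table": table,
        "imputation": imputation,
        "descriptives": descriptives,
        "battery": battery,
        "correlations": correlations,
        "pca": pca,
        "vus_features": vus_features,
        "models": {
            "PCA": pca_model,
            "AA": aa_model,
            "CAR": car_model,
        },
        "predictor_scores": predictor_scores,
        "vus_predictors": vus_predictors,
        "forest": forest,
        "decisions": decisions,
    }

    if config.outdir is not None:
        _write_bundle(config, artifacts, seeds)
    return artifacts


def _write_bundle(
    config: PipelineConfig, artifacts: dict, seeds: np.ndarray
) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts["table"].to_csv(outdir / "cohort.csv")
    artifacts["descriptives"].to_csv(
        outdir / "descriptives.csv", index=False
    )
    battery = artifacts["battery"]
    battery.normality_p.to_csv(outdir / "normality_p.csv")
    battery.variance_homogeneity_p.rename("fligner_p").to_csv(
        outdir / "variance_homogeneity_p.csv"
    )
    pairwise = pd.concat(
        {var: tab for var, tab in battery.pairwise_p.items()},
        names=["variable", "row"],
    ).reset_index(level=0)
    pairwise.to_csv(outdir / "pairwise_p.csv", index=False)
    corr = artifacts["correlations"]
    corr.tau.to_csv(outdir / "kendall_tau.csv")
    corr.p_adjusted.to_csv(outdir / "kendall_p_adjusted.csv")
    pca = artifacts["pca"]
    pd.Series(pca.eigenvalues, name="eigenvalue").to_csv(
        outdir / "pca_eigenvalues.csv", index_label="component"
    )
    pca.scores.to_csv(outdir / "pca_scores.csv")
    artifacts["vus_features"].to_csv(
        outdir / "vus_features.csv", index=False
    )
    artifacts["vus_predictors"].to_csv(
        outdir / "vus_predictors.csv", index=False
    )
    artifacts["forest"].to_csv(outdir / "forest.csv", index=False)
    scores = pd.DataFrame(artifacts["predictor_scores"])
    scores.insert(0, "sample_id", artifacts["table"].data["sample_id"])
    scores.insert(1, "class", artifacts["table"].data["class"])
    scores.to_csv(outdir / "predictor_scores.csv", index=False)

    manifest = {
        "seed": int(config.seed),
        "stage_seeds": [int(s) for s in seeds],
        "class_order": list(config.class_order),
        "vus_B": config.vus_B,
        "ci_level": config.ci_level,
        "tie_rule": config.tie_rule,
        "max_subset_size": config.max_subset_size,
        "occam_ratio": config.occam_ratio,
        "pseudo_response": config.pseudo_response,
        "car_k": config.car_k,
        "delta": config.delta,
        "B_outer": config.B_outer,
        "B_inner": config.B_inner,
        "ci_method": config.ci_method,
        "n_samples": len(artifacts["table"]),
        "class_sizes": artifacts["table"].class_sizes(),
        "imputation": {
            "n_chains": artifacts["imputation"].n_chains,
            "iterations_used": artifacts["imputation"].iterations_used,
            "converged": artifacts["imputation"].converged,
            "n_imputed": len(artifacts["imputation"].imputed_index),
        },
        "pca_retained_k": artifacts["pca"].retained_k,
        "pca_cumulative_variance": artifacts["pca"].cumulative_variance,
        "input": config.input_path or "simulated",
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
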