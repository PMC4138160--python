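"""End-to-end study replica: cohort in, three analysis groups out.

For each analysis group (the full cohort plus closed age bands, each refitted
from scratch — subgroups get their own standardization, PCA and rankings),
the pipeline produces the PCA bundle, variance- and effect-size-sorted PC
rankings, cross-validated accuracy curves, optimal prefix selections under
both rules, the per-variable comparison table and PC-variable correlations,
and a machine-readable summary JSON.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .classify import accuracy_curve, accuracy_curve_leakage_free, select_optimal
from .discrete_features import canonicalize_columns, filter_age_band, validate_feature_table
from .effect_size import effect_size_label, rank_by_effect_size
from .group_stats import pc_variable_correlations, two_sample_tests
from .pca import CovariancePCA, rank_by_variance
from .synthetic_data import FIXTURE_NAMES, generate_feature_cohort, load_cohort_fixture
from .variables import DEMOGRAPHIC_COLUMNS, VARIABLE_NAMES


class AnalysisConfig(BaseModel):
    """Configuration of a full run; all fields overridable from the CLI."""

    source: str = "general"  # fixture name or path to a feature CSV
    label_column: str = "gender"
    age_bands: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {"young": (18.0, 26.0), "older": (55.0, 72.0)}
    )
    ranking_modes: list[str] = Field(default_factory=lambda: ["variance", "effect_size"])
    n_folds: int = 10
    c: float = 1.0
    cohort_seed: int = 0
    fold_seed: int = 0
    leakage: str = "prefit"  # "prefit" (full-sample PCA+ranking) or "fold_internal"
    g_threshold: float = 0.09
    correlation_model: str = "bilateral"
    rho: float = 0.6
    n_top_pcs: int = 3
    outdir: str = "gaitsep_out"

    @field_validator("n_folds")
    @classmethod
    def _folds(cls, v):
        if v < 2:
            raise ValueError("folds must be >= 2")
        return v

    @field_validator("c")
    @classmethod
    def _margin(cls, v):
        if v <= 0:
            raise ValueError("soft-margin parameter c must be > 0")
        return v

    @field_validator("leakage")
    @classmethod
    def _leakage(cls, v):
        if v not in ("prefit", "fold_internal"):
            raise ValueError("leakage must be 'prefit' or 'fold_internal'")
        return v

    def check_bands(self) -> None:
        bands = list(self.age_bands.items())
        for i, (name_i, (lo_i, hi_i)) in enumerate(bands):
            for name_j, (lo_j, hi_j) in bands[i + 1 :]:
                if lo_i <= hi_j and lo_j <= hi_i:
                    warnings.warn(
                        f"age bands {name_i} and {name_j} overlap", stacklevel=2
                    )


def validate_inputs(path) -> tuple[pd.DataFrame, list[str]]:
    """Read and normalize a feature CSV; diagnostics name every violation."""
    table = pd.read_csv(path)
    diagnostics = validate_feature_table(table)
    if any(d.startswith("missing") for d in diagnostics):
        return table, diagnostics
    non_numeric = [
        v for v in VARIABLE_NAMES if not np.issubdtype(table[v].dtype, np.number)
    ]
    if non_numeric:
        diagnostics.append(f"non-numeric columns: {non_numeric}")
        return table, diagnostics
    return canonicalize_columns(table), diagnostics


def load_cohort(config: AnalysisConfig) -> pd.DataFrame:
    """Resolve the configured source into a canonical feature table."""
    if config.source in FIXTURE_NAMES:
        spec = load_cohort_fixture(config.source)
        spec.correlation = config.correlation_model
        spec.rho = config.rho
        return generate_feature_cohort(spec, seed=config.cohort_seed)
    table, diagnostics = validate_inputs(config.source)
    if diagnostics:
        raise ValueError(f"invalid input {config.source}: {'; '.join(diagnostics)}")
    return table


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def analyse_group(
    table: pd.DataFrame, config: AnalysisConfig, group_dir: Path | None = None
) -> dict:
    """Run the full analysis on one group; optionally serialize the bundle."""
    labels = table[config.label_column].to_numpy()
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("group has a single class after filtering")
    features = table[list(VARIABLE_NAMES)]
    pca = CovariancePCA().fit(features)
    summary: dict = {
        "n": int(len(table)),
        "class_counts": {str(c): int(n) for c, n in zip(classes, counts)},
        "n_components": int(pca.n_components_),
        "rankings": {},
    }

    rankings = {}
    for mode in config.ranking_modes:
        ranking = (
            rank_by_effect_size(pca, labels)
            if mode == "effect_size"
            else rank_by_variance(pca)
        )
        rankings[mode] = ranking
        if config.leakage == "fold_internal":
            curve = accuracy_curve_leakage_free(
                features.to_numpy(float), labels, mode=mode,
                n_folds=config.n_folds, c=config.c, seed=config.fold_seed,
            )
        else:
            curve = accuracy_curve(
                pca, ranking, labels,
                n_folds=config.n_folds, c=config.c, seed=config.fold_seed,
            )
        selection = select_optimal(
            curve,
            ranking=ranking if mode == "effect_size" else None,
            g_threshold=config.g_threshold if mode == "effect_size" else None,
        )
        entry = {
            "K": int(curve.mean_accuracy.size),
            "k_argmax": selection["argmax"]["k"],
            "accuracy_at_argmax": selection["argmax"]["accuracy"],
            "cumulative_variance_at_argmax": (
                float(ranking.cumulative_variance[selection["argmax"]["k"] - 1])
            ),
        }
        if "g_threshold" in selection:
            entry["k_g_threshold"] = selection["g_threshold"]["k"]
            entry["accuracy_at_g_threshold"] = selection["g_threshold"]["accuracy"]
        if mode == "effect_size":
            top = ranking.order[: config.n_top_pcs]
            entry["top_pcs"] = [
                {
                    "pc": int(j) + 1,
                    "g": float(ranking.signed_g[j]),
                    "abs_g": float(abs(ranking.signed_g[j])),
                    "label": effect_size_label(ranking.signed_g[j]),
                    "variance_fraction": float(pca.explained_variance_ratio_[j]),
                }
                for j in top
            ]
            entry["variance_of_top_pcs"] = float(
                pca.explained_variance_ratio_[top].sum()
            )
        summary["rankings"][mode] = entry

        if group_dir is not None:
            ranking.to_frame().to_csv(group_dir / f"ranking_{mode}.csv", index=False)
            curve_df = pd.DataFrame(
                {
                    "k": np.arange(1, curve.mean_accuracy.size + 1),
                    "mean_accuracy": curve.mean_accuracy,
                    "cumulative_variance": curve.cumulative_variance,
                    "min_abs_key": curve.min_abs_key,
                }
            )
            for f in range(curve.fold_accuracies.shape[1]):
                curve_df[f"fold_{f}"] = curve.fold_accuracies[:, f]
            curve_df.to_csv(group_dir / f"curve_{mode}.csv", index=False)

    comparison = two_sample_tests(table, labels=labels)
    if "effect_size" in rankings:
        top_pcs = [int(j) + 1 for j in rankings["effect_size"].order[: config.n_top_pcs]]
    else:
        top_pcs = list(range(1, min(config.n_top_pcs, pca.n_components_) + 1))
    correlations = pc_variable_correlations(pca, top_pcs, table)
    summary["n_significant_after_holm"] = int(comparison["significant"].sum())

    if group_dir is not None:
        group_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "eigenvalue": pca.eigenvalues_,
                "variance_fraction": pca.explained_variance_ratio_,
            }
        ).to_csv(group_dir / "eigenvalues.csv", index=False)
        pd.DataFrame(
            pca.components_.T,
            index=list(VARIABLE_NAMES),
            columns=[f"PC{j+1}" for j in range(pca.n_components_)],
        ).to_csv(group_dir / "loadings.csv")
        pd.DataFrame(
            pca.scores_,
            columns=[f"PC{j+1}" for j in range(pca.n_components_)],
        ).assign(subject_id=table["subject_id"].to_numpy()).to_csv(
            group_dir / "scores.csv", index=False
        )
        comparison.to_csv(group_dir / "comparison.csv", index=False)
        correlations.to_csv(group_dir / "correlations.csv", index=False)

    return summary


def run_full_analysis(config: AnalysisConfig, write: bool = True) -> dict:
    """Run every analysis group and return (and optionally write) the summary."""
    config.check_bands()
    table = load_cohort(config)
    outdir = Path(config.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "cohort.csv", index=False)

    summary = {"config": json.loads(config.model_dump_json()), "groups": {}}
    groups: dict[str, pd.DataFrame] = {"general": table}
    for name, (low, high) in config.age_bands.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            groups[name] = filter_age_band(table, low, high)
    for name, sub in groups.items():
        group_dir = outdir / name if write else None
        if group_dir is not None:
            group_dir.mkdir(parents=True, exist_ok=True)
        summary["groups"][name] = analyse_group(sub, config, group_dir)

    summary = _round_floats(summary)
    if write:
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return summary
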