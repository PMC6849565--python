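"""Table I/O, schema validation, run configuration and pipeline orchestration.

All tables are UTF-8 comma-separated CSV with ``.`` decimals, ISO dates and
percentages stored as 0-100 numbers.  ``read_table`` validates a file
against a named schema and reports row-level problems with line numbers;
``run_pipeline`` chains the full analysis (simulate -> classify ->
community metrics -> multifunctionality -> resilience -> screening) and
writes a manifest echoing every parameter, so no default is applied
silently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .community import community_summary
from .grouping import TRAIT_NAMES, cluster_species, verify_lda
from .multifunctionality import multifunctionality_score
from .simulate import MONTHS, GeneratorConfig, simulate_experiment
from .stability import compute_stability
from .screening import screen_and_average

logger = logging.getLogger(__name__)

#: schema name -> (required columns, column -> (kind, bounds))
SCHEMAS: dict[str, dict] = {
    "traits": {
        "columns": ["species_id", *TRAIT_NAMES],
        "numeric": {
            "height": (0.0, None), "sla": (0.0, None),
            "perenniality": (1, 5), "root_architecture": (1, 8),
            "root_depth": (1, 3), "mycorrhizal_affinity": (1, 3),
        },
        "allow_missing": set(TRAIT_NAMES),
    },
    "survey": {
        "columns": ["subplot_id", "survey_month", "species_id", "cover_pct"],
        "numeric": {"cover_pct": (0.0, 100.0)},
        "allow_missing": set(),
    },
    "panel": {
        "columns": ["subplot_id", "time_point", "function_name", "value"],
        "numeric": {"value": (None, None)},
        "allow_missing": {"value"},
    },
    "pairs": {
        "columns": ["plot_id", "function_name", "control_july", "drought_july",
                    "control_september", "drought_september"],
        "numeric": {c: (None, None) for c in
                    ["control_july", "drought_july", "control_september",
                     "drought_september"]},
        "allow_missing": set(),
    },
    "rain": {
        "columns": ["date", "rain_mm"],
        "numeric": {"rain_mm": (0.0, None)},
        "allow_missing": set(),
    },
}


class SchemaError(ValueError):
    """The file cannot be interpreted under the requested schema."""


class RowErrors(ValueError):
    """Individual rows failed validation; ``errors`` lists line messages."""

    def __init__(self, errors: list[str]):
        super().__init__(f"{len(errors)} row-level errors; first: {errors[0]}")
        self.errors = errors


def read_table(path, schema_name: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Row failures are collected (with 1-based data line numbers, header is
    line 1) and raised together as :class:`RowErrors`.
    """
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}")
    schema = SCHEMAS[schema_name]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in schema["columns"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    errors: list[str] = []
    for col, (lo, hi) in schema["numeric"].items():
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad_parse = num.isna() & raw.notna()
        for idx in df.index[bad_parse]:
            errors.append(f"line {idx + 2}: {col}={raw[idx]!r} not numeric")
        if num.isna().any() and col not in schema["allow_missing"]:
            for idx in df.index[num.isna() & ~bad_parse]:
                errors.append(f"line {idx + 2}: {col} missing")
        out_of_range = pd.Series(False, index=df.index)
        if lo is not None:
            out_of_range |= num < lo
        if hi is not None:
            out_of_range |= num > hi
        for idx in df.index[out_of_range.fillna(False)]:
            errors.append(f"line {idx + 2}: {col}={num[idx]} out of range")
        df[col] = num
    if errors:
        raise RowErrors(errors)
    return df


@dataclass
class RunConfig:
    """Parameters of a full pipeline run; every field is echoed in the manifest."""

    seed: int = 1
    k: int = 3
    cluster_method: str = "ward"
    threshold: float = 0.5
    dendrogram_cut: float = 0.7
    d0_convention: str = "difference"
    wet_threshold_mm: float = 1.0
    return_period_years: float = 100.0
    screen_function: str = "mineralization"
    screen_time_point: str = "July"
    n_trees: int = 1000
    top_m: int = 3
    out_dir: str = "traitsoil_run"
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        if self.dendrogram_cut <= 0:
            raise ValueError("dendrogram cut must be positive")
        if self.d0_convention not in ("difference", "value"):
            raise ValueError("d0_convention must be 'difference' or 'value'")
        if self.return_period_years <= 1:
            raise ValueError("return period must exceed 1 year")
        if self.screen_time_point not in MONTHS:
            raise ValueError(f"time point must be one of {MONTHS}")


def run_pipeline(config: RunConfig) -> dict:
    """Simulate an experiment and run every analysis stage over it.

    Returns (and writes) a manifest with the package version, seed, full
    parameter echo and per-stage row counts; any stage failure raises with
    the stage name attached.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "traitsoil", "version": __version__,
        "parameters": asdict(config), "stages": {},
    }
    stage = "simulate"
    try:
        exp = simulate_experiment(GeneratorConfig(seed=config.seed))
        exp.traits.to_csv(out / "traits.csv", index=False)
        exp.survey.to_csv(out / "survey.csv", index=False)
        exp.panel.to_csv(out / "panel.csv", index=False)
        exp.pairs.to_csv(out / "pairs.csv", index=False)
        exp.layout.to_csv(out / "layout.csv", index=False)
        manifest["stages"][stage] = {"species": len(exp.traits),
                                     "subplots": exp.layout["subplot_id"].nunique()}

        stage = "classify"
        assignment = cluster_species(exp.traits, k=config.k,
                                     method=config.cluster_method,
                                     seed=config.seed)
        verified = verify_lda(exp.traits, assignment)
        verified.table.to_csv(out / "groups.csv", index=False)
        manifest["stages"][stage] = {
            "agreement_pct": verified.agreement_pct,
            "group_sizes": {str(k): v for k, v in verified.group_sizes().items()},
        }

        stage = "community_metrics"
        summary = community_summary(exp.survey, exp.traits)
        summary.to_csv(out / "community_metrics.csv", index=False)
        manifest["stages"][stage] = {"rows": len(summary)}

        stage = "multifunctionality"
        scores = []
        for month in MONTHS:
            res = multifunctionality_score(exp.panel, month,
                                           threshold=config.threshold,
                                           cut=config.dendrogram_cut)
            scores.append(res.scores)
        mf = pd.concat(scores, ignore_index=True)
        mf.to_csv(out / "multifunctionality.csv", index=False)
        manifest["stages"][stage] = {"rows": len(mf)}

        stage = "resilience"
        stability = compute_stability(exp.pairs, d0_convention=config.d0_convention)
        stability.to_csv(out / "stability.csv", index=False)
        manifest["stages"][stage] = {"rows": len(stability)}

        stage = "screen"
        month = config.screen_time_point
        fvals = exp.panel.query(
            "time_point == @month and function_name == @config.screen_function"
        ).set_index("subplot_id")["value"]
        merged = exp.predictors.join(fvals.rename("response")).join(
            exp.layout.drop_duplicates("subplot_id").set_index("subplot_id")
            [["block", "plot_id"]]).reset_index()
        ranking, model_set = screen_and_average(
            merged, "response", list(exp.predictors.columns),
            n_trees=config.n_trees, seed=config.seed, top_m=config.top_m)
        ranking.to_csv(out / "screening.csv", index=False)
        model_set.models.to_csv(out / "models.csv", index=False)
        model_set.averaged.to_csv(out / "averaged_coefficients.csv", index=False)
        manifest["stages"][stage] = {
            "top_predictors": ranking.head(config.top_m)["predictor_name"].tolist(),
            "retained_models": len(model_set.retained_ids),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("pipeline complete: %d stages", len(manifest["stages"]))
    return manifest
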