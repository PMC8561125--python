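"""File I/O, run configuration and the end-to-end pipeline.

The long-format CSV schema is
``subject_id,cohort,sex,race,age,bmi,bmi_pct,sbp,dbp,bp_pct,total_chol,
glucose,bp_med,lipid_med,glucose_med,cvh_score`` (unused columns empty).
``run_pipeline`` executes the full analysis — score, completeness filter,
segmented fit (overall and optionally stratified), model comparison,
fixed-knot interaction model, descriptive tables — into a run directory with
a manifest, deterministically given the configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .reporting import baseline_table, compare_models, fit_piecewise_interaction, metric_means_at_ages
from .scoring import apply_completeness_filter, score_dataset
from .segmented import SegmentedModelSpec, fit_segmented, fitted_mean_curve
from .simulate import SCORE_COLUMNS, generate_raw_metrics, generate_scores, preset

__all__ = [
    "RunConfig",
    "FormatError",
    "read_long_csv",
    "write_long_csv",
    "run_pipeline",
]

log = logging.getLogger("cvh_windows")

MANDATORY_COLUMNS = ("subject_id", "age")
_NUMERIC_COLUMNS = (
    "age", "bmi", "bmi_pct", "sbp", "dbp", "bp_pct", "total_chol", "glucose",
    "cvh_score",
)
_BOOL_COLUMNS = ("bp_med", "lipid_med", "glucose_med")


class FormatError(ValueError):
    """Fatal input-format problem (missing mandatory columns, mass failure)."""


def read_long_csv(path) -> pd.DataFrame:
    """Read a long-format exam CSV with row-level validation.

    Rows with an unparseable or out-of-range age are dropped with a logged
    warning; more than 50% failures (of a nonempty file) is fatal.  Extra
    columns are kept but warned about.  Missing mandatory columns raise
    :class:`FormatError`.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {missing}")
    extra = [c for c in df.columns if c not in SCORE_COLUMNS]
    if extra:
        log.warning("ignoring unrecognized column(s): %s", extra)
    n_in = len(df)
    if n_in == 0:
        log.warning("empty input file %s", path)
        return df
    for c in _NUMERIC_COLUMNS:
        if c in df.columns:
            df[c] = pd.to_numeric(df[c], errors="coerce")
    for c in _BOOL_COLUMNS:
        if c in df.columns:
            mapped = df[c].map({True: True, False: False, "True": True,
                                "False": False, 1: True, 0: False,
                                "1": True, "0": False})
            df[c] = mapped.where(mapped.notna(), False).astype(bool)
    ok = df["age"].notna() & (df["age"] >= 0) & (df["age"] < 120)
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("dropping %d of %d row(s) with invalid age", n_bad, n_in)
        if n_bad > 0.5 * n_in:
            raise FormatError(
                f"{n_bad}/{n_in} rows failed validation; refusing to continue"
            )
    return df[ok].reset_index(drop=True)


def write_long_csv(df: pd.DataFrame, path) -> None:
    """Write a dataset in the canonical column order (absent columns empty)."""
    out = pd.DataFrame({c: df[c] if c in df.columns else np.nan for c in SCORE_COLUMNS})
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Exactly one of ``input_path`` / ``preset_name`` must be given.
    """

    input_path: str | None = None
    preset_name: str | None = None
    n_subjects: int | None = None
    raw_metrics: bool = False
    covariates: tuple[str, ...] = ("sex", "race", "cohort")
    n_changepoints: int = 2
    stratify_by: str | None = None
    interaction_group: str = "sex"
    knots: tuple[float, float] | None = None
    seed: int = 0
    min_gap: float = 3.0
    output_dir: str = "cvh_run"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.preset_name is None):
            raise ValueError("specify exactly one of input_path / preset_name")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("covariates", "knots"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


STAGES = (
    "score",
    "filter",
    "segmented_fit",
    "model_comparison",
    "piecewise_interaction",
    "descriptive_tables",
)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages into ``config.output_dir`` and return that path.

    Any stage failure aborts with the stage name in the raised error; partial
    outputs and the manifest (with the failed stage recorded) are persisted.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setLevel(logging.INFO)
    log.addHandler(handler)
    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages_completed": [],
    }
    completed = manifest["stages_completed"]

    def save_manifest() -> None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    try:
        # -- stage: score ------------------------------------------------
        if config.preset_name is not None:
            gc = preset(config.preset_name, seed=config.seed,
                        n_subjects=config.n_subjects)
            if config.raw_metrics:
                from dataclasses import replace

                raw = generate_raw_metrics(replace(gc, raw_metric_mode=True))
                data, report = score_dataset(raw, drop_incomplete=False)
            else:
                data = generate_scores(gc)
        else:
            data = read_long_csv(config.input_path)
            if "cvh_score" not in data.columns or data["cvh_score"].isna().all():
                data, _ = score_dataset(data, drop_incomplete=False)
        write_long_csv(data, out / "scored_data.csv")
        completed.append("score")
        log.info("scored %d exam(s)", len(data))

        # -- stage: filter -----------------------------------------------
        data, report = apply_completeness_filter(data)
        with open(out / "inclusion_report.json", "w") as fh:
            json.dump(asdict(report), fh, indent=2)
        if len(data) == 0:
            raise RuntimeError("no complete exams after the inclusion filter")
        completed.append("filter")
        log.info(
            "completeness filter: %d/%d exams, %d/%d subjects retained",
            report.n_records_complete, report.n_records_in,
            report.n_subjects_retained, report.n_subjects_in,
        )

        usable_covs = tuple(
            c for c in config.covariates if c in data.columns and data[c].nunique() > 1
        )

        # -- stage: segmented fit ----------------------------------------
        spec = SegmentedModelSpec(
            n_changepoints=config.n_changepoints,
            fixed_covariates=usable_covs,
            min_gap=config.min_gap,
        )
        fit = fit_segmented(data, spec)
        fit.to_json(out / "segmented_fit.json")
        ages = np.linspace(data["age"].min(), data["age"].max(), 200)
        fitted_mean_curve(fit, ages).to_csv(out / "fitted_curve.csv", index=False)
        if config.stratify_by:
            for level, sub in data.groupby(config.stratify_by):
                sub_covs = tuple(
                    c for c in usable_covs
                    if c != config.stratify_by and sub[c].nunique() > 1
                )
                sfit = fit_segmented(
                    sub.reset_index(drop=True),
                    SegmentedModelSpec(
                        n_changepoints=config.n_changepoints,
                        fixed_covariates=sub_covs,
                        min_gap=config.min_gap,
                    ),
                )
                sfit.to_json(out / f"segmented_fit_{config.stratify_by}_{level}.json")
        completed.append("segmented_fit")
        log.info("estimated change points: %s", np.round(fit.psi, 3).tolist())

        # -- stage: model comparison -------------------------------------
        comparison = compare_models(data, usable_covs, min_gap=config.min_gap)
        comparison.table.to_csv(out / "model_comparison.csv", index=False)
        comparison.lrt.to_csv(out / "model_comparison_lrt.csv", index=False)
        completed.append("model_comparison")
        log.info("best model by AIC: %s; by BIC: %s",
                 comparison.best_aic, comparison.best_bic)

        # -- stage: piecewise interaction --------------------------------
        knots = config.knots
        if knots is None:
            # default to the rounded estimated change points when available
            knots = tuple(np.round(fit.psi)) if len(fit.psi) == 2 else (17.0, 37.0)
        adjust = tuple(c for c in usable_covs if c != config.interaction_group)
        pw = fit_piecewise_interaction(
            data, knots=knots, group=config.interaction_group, adjust=adjust
        )
        with open(out / "piecewise_interaction.json", "w") as fh:
            json.dump(pw.to_dict(), fh, indent=2)
        pw.slopes.to_csv(out / "segment_slopes_by_group.csv", index=False)
        pw.differences.to_csv(out / "segment_slope_differences.csv", index=False)
        completed.append("piecewise_interaction")

        # -- stage: descriptive tables -----------------------------------
        baseline_table(data).to_csv(out / "baseline_table.csv", index=False)
        if data.get("bmi") is not None and data["bmi"].notna().any():
            metric_means_at_ages(data).to_csv(
                out / "metric_means_at_ages.csv", index=False
            )
        completed.append("descriptive_tables")
        save_manifest()
        log.info("pipeline complete: %d stage(s)", len(completed))
        return out
    except Exception as exc:
        manifest["failed_stage"] = STAGES[len(completed)] if len(completed) < len(STAGES) else "unknown"
        manifest["error"] = str(exc)
        save_manifest()
        raise RuntimeError(
            f"pipeline failed at stage {manifest['failed_stage']!r}: {exc}"
        ) from exc
    finally:
        log.removeHandler(handler)
        handler.close()
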