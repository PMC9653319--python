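"""Cohort I/O, study configuration and the end-to-end pipeline.

A cohort is a plain :class:`pandas.DataFrame` with one row per eye
(columns: ``subject_id, eye, group, age_years, iop_mmhg, md_db, arnflt_um,
mag_uv, magd_uv`` and, once computed, ``ergc_csfi``).  :func:`read_cohort_csv`
validates files row by row; :func:`run_study` executes the complete analysis
— training/validation split, mixed-model fits for both PERG parameters,
cross-validation, group statistics (ANOVA, Games-Howell, Welch t, Pearson,
ROC) and the loss-accounting table — and returns a :class:`StudyReport`
whose tables round only at render time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort_stats as cs
from .linear_models import (
    PERG_COLUMNS,
    LinearRGCModel,
    annual_loss_rate,
    builtin_models,
    cross_validate,
    fit_glmm,
    proportional_loss,
    split_cohort,
)
from .synthetic_data import GROUP_ORDER, PHYSIO_BOUNDS

__all__ = [
    "REQUIRED_COLUMNS",
    "CohortValidationError",
    "StudyConfig",
    "StudyReport",
    "read_cohort_csv",
    "write_cohort_csv",
    "validate_cohort",
    "run_study",
]

logger = logging.getLogger("rgcest")

REQUIRED_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "eye",
    "group",
    "age_years",
    "arnflt_um",
    "mag_uv",
    "magd_uv",
    "md_db",
)

#: Variables summarised per group / per split, column -> display label.
_SUMMARY_VARS: dict[str, str] = {
    "age_years": "Age (years)",
    "iop_mmhg": "IOP (mmHg)",
    "md_db": "24-2 MD (dB)",
    "arnflt_um": "ARNFLT (um)",
    "mag_uv": "Mag (uV)",
    "magd_uv": "MagD (uV)",
    "ergc_csfi": "eRGC_CSFI",
}

_ESTIMATE_VARS: dict[str, str] = {
    "ergc_mag": "eRGC_Mag",
    "ergc_magd": "eRGC_MagD",
}


class CohortValidationError(ValueError):
    """One or more cohort rows violate the record invariants."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid cohort:\n" + "\n".join(problems))


def validate_cohort(cohort: pd.DataFrame) -> list[str]:
    """Return a list of human-readable violations (empty if valid).

    Row numbers refer to the data rows of the frame (0-based, header
    excluded), matching what :func:`read_cohort_csv` reports.
    """
    problems: list[str] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
    if missing:
        return [f"missing required columns: {missing}"]
    dup = cohort.duplicated(subset=["subject_id", "eye"], keep=False)
    for idx in cohort.index[dup]:
        row = cohort.loc[idx]
        problems.append(
            f"row {idx}: duplicate (subject, eye) pair "
            f"({row['subject_id']!r}, {row['eye']!r})"
        )
    for idx, row in cohort.iterrows():
        if row["eye"] not in ("OD", "OS"):
            problems.append(f"row {idx}: eye must be OD or OS, got {row['eye']!r}")
        if row["group"] not in GROUP_ORDER:
            problems.append(
                f"row {idx}: group must be one of {GROUP_ORDER}, got {row['group']!r}"
            )
        for col in ("age_years", "arnflt_um", "mag_uv", "magd_uv", "md_db"):
            val = row[col]
            if pd.isna(val):
                problems.append(f"row {idx}: {col} is missing")
                continue
            lo, hi = PHYSIO_BOUNDS[col]
            if not (lo <= val <= hi):
                problems.append(
                    f"row {idx}: {col}={val} outside physiologic bounds [{lo}, {hi}]"
                )
    # both eyes of a subject must share one age
    for subj, grp in cohort.groupby("subject_id"):
        if grp["age_years"].nunique() > 1:
            problems.append(
                f"subject {subj!r}: eyes disagree on age {sorted(grp['age_years'])}"
            )
    return problems


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a one-row-per-eye cohort CSV."""
    cohort = pd.read_csv(path)
    problems = validate_cohort(cohort)
    if problems:
        raise CohortValidationError(problems)
    logger.info("read_cohort_csv: %d eyes, %d subjects from %s",
                len(cohort), cohort["subject_id"].nunique(), path)
    return cohort


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one end-to-end study run."""

    seed: int | None = None
    split_fraction: float = 0.6
    split_unit: str = "eye"  # or "subject"
    variant: str = "corrected"
    use_builtin_models: bool = False  # bypass fitting, use bundled estimators
    outcome: str = "ergc_csfi"

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


@dataclass
class StudyReport:
    """All study tables plus the provenance header.

    Tables hold unrounded values; :meth:`to_markdown` and :meth:`write_csv`
    apply display rounding only at render time.
    """

    header: dict
    group_summary: pd.DataFrame  # per-variable group means/SDs + ANOVA
    split_summary: pd.DataFrame  # Welch t per variable, training vs validation
    model_table: pd.DataFrame  # coefficients, SEs, p, R² per model
    pairwise_table: pd.DataFrame  # Games-Howell contrasts per variable
    roc_table: pd.DataFrame  # AUC per variable per group contrast
    loss_table: pd.DataFrame  # percent losses and per-year rates
    models: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "group_summary": self.group_summary,
            "split_summary": self.split_summary,
            "model_table": self.model_table,
            "pairwise_table": self.pairwise_table,
            "roc_table": self.roc_table,
            "loss_table": self.loss_table,
        }

    def write_csv(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "header.yaml", "w") as fh:
            yaml.safe_dump(self.header, fh, sort_keys=True)
        for name, table in self.tables().items():
            table.to_csv(directory / f"{name}.csv", index=False, float_format="%.6g")

    def to_markdown(self) -> str:
        parts = ["# Study report", ""]
        parts += [f"- {k}: {v}" for k, v in sorted(self.header.items())]
        titles = {
            "group_summary": "Group summary (ANOVA)",
            "split_summary": "Training vs validation (Welch t)",
            "model_table": "Mixed-model RGC estimators",
            "pairwise_table": "Games-Howell pairwise comparisons",
            "roc_table": "ROC analysis",
            "loss_table": "Proportional losses",
        }
        for name, table in self.tables().items():
            parts += ["", f"## {titles[name]}", "", table.round(4).to_markdown(index=False)]
        return "\n".join(parts) + "\n"


def _grouped_stat(cohort, col, fn, default=np.nan):
    """Apply a per-variable test defensively; degenerate data yields NaN."""
    try:
        return fn()
    except ValueError as exc:
        logger.warning("stat on %s skipped: %s", col, exc)
        return default


def run_study(cohort: pd.DataFrame, config: StudyConfig | None = None) -> StudyReport:
    """Run the full structure-function study pipeline on a cohort.

    Stages (each logged with its record counts): validation; outcome
    pass-through (``ergc_csfi`` must be present — compute it first with the
    CSFI chain if starting from visual fields); training/validation split;
    one mixed-model fit per PERG parameter on the training eyes (or the
    bundled estimators when ``use_builtin_models``); prediction and
    training/validation R²; group statistics; loss accounting.

    Inferential statistics on variables that are degenerate in the given
    cohort (e.g. zero variance) are reported as NaN rather than aborting the
    pipeline; the strict per-operation error contracts live in
    :mod:`rgcest.cohort_stats`.
    """
    config = config or StudyConfig()
    problems = validate_cohort(cohort)
    if problems:
        raise CohortValidationError(problems)
    if config.outcome not in cohort.columns:
        raise ValueError(
            f"stage outcome: column {config.outcome!r} missing - compute the "
            "CSFI estimate (rgcest.csfi) before running the study"
        )
    cohort = cohort.reset_index(drop=True)
    logger.info("run_study: %d eyes, %d subjects", len(cohort),
                cohort["subject_id"].nunique())

    # --- split ------------------------------------------------------------
    split = split_cohort(
        cohort, fraction=config.split_fraction, seed=config.seed, unit=config.split_unit
    )
    train = cohort[split.training_mask(cohort)]
    valid = cohort[split.validation_mask(cohort)]
    logger.info("stage split: %d training / %d validation eyes", len(train), len(valid))

    # --- models -----------------------------------------------------------
    models: dict[str, LinearRGCModel] = {}
    if config.use_builtin_models:
        models["Mag"], models["MagD"] = builtin_models()
        model_source = "builtin"
    else:
        for perg in PERG_COLUMNS:
            models[perg] = fit_glmm(train, perg, outcome=config.outcome)
        model_source = "fitted"
    logger.info("stage models: %s (Mag, MagD)", model_source)

    preds = {perg: m.predict_frame(cohort) for perg, m in models.items()}
    cohort = cohort.assign(
        ergc_mag=preds["Mag"], ergc_magd=preds["MagD"]
    )
    train = cohort[split.training_mask(cohort)]
    valid = cohort[split.validation_mask(cohort)]

    r2: dict[str, dict[str, float]] = {}
    for perg, m in models.items():
        r2[perg] = {}
        for name, subset in (("training", train), ("validation", valid)):
            r2[perg][name] = _grouped_stat(
                subset, perg, lambda s=subset, m=m: cross_validate(m, s, config.outcome)
            )

    # --- model table ------------------------------------------------------
    model_rows = []
    for perg, m in models.items():
        for term, coef in m.coefficients().items():
            model_rows.append(
                {
                    "model": f"eRGC_{perg}",
                    "term": term,
                    "coefficient": coef,
                    "se": (m.se or {}).get(term, np.nan),
                    "p_value": (m.p_values or {}).get(term, np.nan),
                    "r2_training": r2[perg]["training"],
                    "r2_validation": r2[perg]["validation"],
                }
            )
    model_table = pd.DataFrame(model_rows)

    # --- group summary (ANOVA) -------------------------------------------
    groups_present = [g for g in GROUP_ORDER if g in set(cohort["group"])]
    rows = []
    all_vars = {**_SUMMARY_VARS, **_ESTIMATE_VARS}
    for col, label in all_vars.items():
        if col not in cohort.columns:
            continue
        row = {"variable": label}
        for g in groups_present:
            vals = cohort.loc[cohort["group"] == g, col]
            row[f"mean_{g}"] = vals.mean()
            row[f"sd_{g}"] = vals.std(ddof=1)
            row[f"n_{g}"] = len(vals)
        res = _grouped_stat(
            cohort, col,
            lambda c=col: cs.one_way_anova(cohort[c].to_numpy(), cohort["group"].to_numpy()),
        )
        if isinstance(res, cs.AnovaResult):
            row.update(F=res.f_statistic, p_value=res.p_value, eta_squared=res.eta_squared)
        else:
            row.update(F=np.nan, p_value=np.nan, eta_squared=np.nan)
        rows.append(row)
    group_summary = pd.DataFrame(rows)

    # --- split summary (Welch t) -----------------------------------------
    rows = []
    for col, label in all_vars.items():
        if col not in cohort.columns:
            continue
        a = train[col].to_numpy(float)
        b = valid[col].to_numpy(float)
        row = {
            "variable": label,
            "mean_training": a.mean() if a.size else np.nan,
            "sd_training": np.std(a, ddof=1) if a.size > 1 else np.nan,
            "mean_validation": b.mean() if b.size else np.nan,
            "sd_validation": np.std(b, ddof=1) if b.size > 1 else np.nan,
        }
        res = _grouped_stat(cohort, col, lambda a=a, b=b: cs.welch_t(a, b))
        if isinstance(res, tuple):
            row.update(t=res[0], df=res[1], p_value=res[2])
        else:
            row.update(t=np.nan, df=np.nan, p_value=np.nan)
        rows.append(row)
    split_summary = pd.DataFrame(rows)

    # --- Games-Howell pairwise -------------------------------------------
    rows = []
    for col, label in all_vars.items():
        if col not in cohort.columns:
            continue
        comps = _grouped_stat(
            cohort, col,
            lambda c=col: cs.games_howell(
                cohort[c].to_numpy(), cohort["group"].to_numpy(), group_order=groups_present
            ),
            default=[],
        )
        for comp in comps:
            rows.append(
                {
                    "variable": label,
                    "group_a": comp.group_a,
                    "group_b": comp.group_b,
                    "mean_difference": comp.mean_difference,
                    "se": comp.se,
                    "df": comp.df,
                    "q": comp.statistic,
                    "p_value": comp.p_value,
                }
            )
    pairwise_table = pd.DataFrame(rows)

    # --- ROC --------------------------------------------------------------
    rows = []
    contrasts = [c for c in (("healthy", "GS"), ("GS", "PPG")) if
                 set(c) <= set(groups_present)]
    roc_vars = {k: v for k, v in all_vars.items()
                if k in ("arnflt_um", "mag_uv", "magd_uv", "ergc_csfi",
                         "ergc_mag", "ergc_magd")}
    for col, label in roc_vars.items():
        if col not in cohort.columns:
            continue
        for ga, gb in contrasts:
            sub = cohort[cohort["group"].isin((ga, gb))]
            res = _grouped_stat(
                cohort, col,
                lambda s=sub, c=col: cs.roc_auc(s[c].to_numpy(), s["group"].to_numpy()),
            )
            row = {"variable": label, "contrast": f"{ga} vs {gb}"}
            if isinstance(res, cs.RocResult):
                row.update(auc=res.auc, p_value=res.p_value, direction=res.direction)
            else:
                row.update(auc=np.nan, p_value=np.nan, direction="")
            rows.append(row)
    roc_table = pd.DataFrame(rows)

    # --- loss accounting --------------------------------------------------
    rows = []
    if "healthy" in groups_present:
        healthy = cohort[cohort["group"] == "healthy"]
        others = [g for g in groups_present if g != "healthy"]
        for col, label in {**{k: v for k, v in _SUMMARY_VARS.items()
                              if k in ("arnflt_um", "mag_uv", "magd_uv", "ergc_csfi")},
                           **_ESTIMATE_VARS}.items():
            if col not in cohort.columns:
                continue
            ref = healthy[col].mean()
            row = {"variable": label, "mean_healthy": ref}
            for g in others:
                gm = cohort.loc[cohort["group"] == g, col].mean()
                row[f"mean_{g}"] = gm
                row[f"loss_pct_{g}"] = proportional_loss(ref, gm)
            rows.append(row)
        for perg, m in models.items():
            ref = float(np.mean(m.predict_frame(healthy)))
            row = {"variable": f"eRGC_{perg} per year",
                   "mean_healthy": ref}
            for g in others:
                row[f"mean_{g}"] = abs(m.coef_age)
                row[f"loss_pct_{g}"] = annual_loss_rate(m, ref)
            rows.append(row)
    loss_table = pd.DataFrame(rows)

    header = {
        "n_eyes": int(len(cohort)),
        "n_subjects": int(cohort["subject_id"].nunique()),
        "seed": config.seed,
        "variant": config.variant,
        "split_unit": config.split_unit,
        "split_fraction": config.split_fraction,
        "n_training": int(len(train)),
        "n_validation": int(len(valid)),
        "model_source": model_source,
        "outcome": config.outcome,
    }
    return StudyReport(
        header=header,
        group_summary=group_summary,
        split_summary=split_summary,
        model_table=model_table,
        pairwise_table=pairwise_table,
        roc_table=roc_table,
        loss_table=loss_table,
        models=models,
    )
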