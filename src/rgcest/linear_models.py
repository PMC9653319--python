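"""Linear RGC estimators from age, RNFL thickness and pattern-ERG amplitude.

An eye's CSFI-estimated retinal ganglion cell count can be approximated by a
three-covariate affine model

    eRGC = intercept + coef_age*age + coef_arnflt*ARNFLT + coef_perg*PERG

where PERG is one steady-state pattern-ERG amplitude parameter: Mag (µV, the
amplitude of the response component at the stimulus reversal rate) or MagD
(µV, the phase-consistency-adjusted amplitude).  Two such reference models,
one per PERG parameter, are bundled (:func:`builtin_models`) with
coefficients from a restricted-maximum-likelihood mixed-model fit to a pilot
glaucoma structure-function cohort; new models can be fitted to any cohort
with :func:`fit_glmm`, which handles the two correlated eyes of each subject
with a per-subject random intercept.

The module also carries the derivation machinery around such models:
reproducible training/validation splits, cross-validation R², and the
loss-accounting summaries (percent loss of a measure relative to healthy
eyes, and the model-implied annual age-related RGC loss rate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

from ._utils import round_half_away

__all__ = [
    "LinearRGCModel",
    "SplitSpec",
    "LossSummary",
    "FitError",
    "SingularDesignError",
    "ConvergenceError",
    "PERG_COLUMNS",
    "REPORTED_MODEL_GROUP_MEANS",
    "builtin_models",
    "predict_rgc",
    "fit_glmm",
    "split_cohort",
    "cross_validate",
    "proportional_loss",
    "annual_loss_rate",
    "loss_summary",
]

#: Cohort-frame column holding each PERG parameter.
PERG_COLUMNS: dict[str, str] = {"Mag": "mag_uv", "MagD": "magd_uv"}

#: Reference group means of the two bundled estimators over the pilot cohort
#: (healthy / glaucoma-suspect / preperimetric-glaucoma eyes).  These anchor
#: the loss-accounting checks and the worked examples.
REPORTED_MODEL_GROUP_MEANS: dict[str, dict[str, float]] = {
    "Mag": {"healthy": 1_068_581.0, "GS": 924_701.0, "PPG": 723_352.0},
    "MagD": {"healthy": 1_070_825.0, "GS": 927_134.0, "PPG": 718_722.0},
}


class FitError(RuntimeError):
    """Mixed-model estimation failed."""


class SingularDesignError(FitError):
    """The fixed-effects design matrix is rank deficient."""


class ConvergenceError(FitError):
    """The optimiser did not converge; the message carries the trace."""


@dataclass(frozen=True)
class LinearRGCModel:
    """An affine RGC-count estimator with optional mixed-model metadata.

    Coefficients are stored at full precision; :meth:`rounded_coefficients`
    derives the display form (integers, halves away from zero).  Variance
    components (``var_subject``, the random-intercept variance, and
    ``var_resid``) and per-coefficient standard errors are populated by
    :func:`fit_glmm` and by the bundled models where known.
    """

    perg_parameter: str
    intercept: float
    coef_age: float
    coef_arnflt: float
    coef_perg: float
    se: Mapping[str, float] | None = None
    p_values: Mapping[str, float] | None = None
    var_subject: float | None = None
    var_resid: float | None = None

    def __post_init__(self) -> None:
        if self.perg_parameter not in PERG_COLUMNS:
            raise ValueError(
                f"perg_parameter must be one of {sorted(PERG_COLUMNS)}, "
                f"got {self.perg_parameter!r}"
            )

    # -- prediction ---------------------------------------------------------
    def predict(self, age_years, arnflt_um, perg_uv):
        """Predicted RGC count; vectorises over array inputs."""
        return (
            self.intercept
            + self.coef_age * np.asarray(age_years, dtype=float)
            + self.coef_arnflt * np.asarray(arnflt_um, dtype=float)
            + self.coef_perg * np.asarray(perg_uv, dtype=float)
        )

    def predict_frame(self, cohort: pd.DataFrame) -> np.ndarray:
        """Predict for every row of a cohort frame (one row per eye)."""
        perg_col = PERG_COLUMNS[self.perg_parameter]
        return np.asarray(
            self.predict(cohort["age_years"], cohort["arnflt_um"], cohort[perg_col])
        )

    # -- presentation / persistence ----------------------------------------
    def coefficients(self) -> dict[str, float]:
        return {
            "intercept": self.intercept,
            "age_years": self.coef_age,
            "arnflt_um": self.coef_arnflt,
            PERG_COLUMNS[self.perg_parameter]: self.coef_perg,
        }

    def rounded_coefficients(self) -> dict[str, float]:
        """Display coefficients rounded to integers, halves away from zero."""
        return {k: round_half_away(v) for k, v in self.coefficients().items()}

    def formula(self) -> str:
        r = self.rounded_coefficients()
        perg = self.perg_parameter
        return (
            f"eRGC_{perg} = {r['intercept']:,.0f} - ({abs(r['age_years']):,.0f}*Age)"
            f" + ({r['arnflt_um']:,.0f}*ARNFLT) + ({r[PERG_COLUMNS[perg]]:,.0f}*{perg})"
        )

    def to_dict(self) -> dict:
        d = {
            "perg_parameter": self.perg_parameter,
            "intercept": self.intercept,
            "coef_age": self.coef_age,
            "coef_arnflt": self.coef_arnflt,
            "coef_perg": self.coef_perg,
        }
        if self.se is not None:
            d["se"] = dict(self.se)
        if self.p_values is not None:
            d["p_values"] = dict(self.p_values)
        if self.var_subject is not None:
            d["var_subject"] = self.var_subject
        if self.var_resid is not None:
            d["var_resid"] = self.var_resid
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "LinearRGCModel":
        return cls(**{k: v for k, v in d.items()})

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "LinearRGCModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def builtin_models() -> tuple[LinearRGCModel, LinearRGCModel]:
    """The two bundled reference estimators (Mag model, MagD model)."""
    mag = LinearRGCModel(
        perg_parameter="Mag",
        intercept=401_341.71,
        coef_age=-6268.04,
        coef_arnflt=8899.32,
        coef_perg=58_610.30,
        se={
            "intercept": 155_818.98,
            "age_years": 991.91,
            "arnflt_um": 1615.10,
            "mag_uv": 24_744.92,
        },
        p_values={
            "intercept": 0.019,
            "age_years": 0.001,
            "arnflt_um": 0.001,
            "mag_uv": 0.027,
        },
    )
    magd = LinearRGCModel(
        perg_parameter="MagD",
        intercept=405_528.50,
        coef_age=-6091.65,
        coef_arnflt=9018.93,
        coef_perg=53_492.96,
        se={
            "intercept": 157_900.55,
            "age_years": 998.267,
            "arnflt_um": 1631.04,
            "magd_uv": 24_090.70,
        },
        p_values={
            "intercept": 0.019,
            "age_years": 0.001,
            "arnflt_um": 0.001,
            "magd_uv": 0.027,
        },
    )
    return mag, magd


def predict_rgc(
    model: LinearRGCModel, age_years, arnflt_um, perg_uv
):
    """Functional alias for :meth:`LinearRGCModel.predict`."""
    return model.predict(age_years, arnflt_um, perg_uv)


# ---------------------------------------------------------------------------
# Mixed-model fitting
# ---------------------------------------------------------------------------

def fit_glmm(
    cohort: pd.DataFrame,
    perg_parameter: str,
    outcome: str = "ergc_csfi",
    covariates: Sequence[str] | None = None,
    reml: bool = True,
) -> LinearRGCModel:
    """Fit a linear mixed model with a per-subject random intercept.

    Both eyes of a subject are treated as repeated measures sharing one
    random intercept, which absorbs the within-subject inter-eye correlation
    of the outcome.  Fixed effects default to age, average RNFL thickness
    and the chosen PERG amplitude.  Estimation is restricted maximum
    likelihood (REML) via :class:`statsmodels.regression.mixed_linear_model.MixedLM`.

    Raises
    ------
    SingularDesignError
        If the fixed-effects design is rank deficient (e.g. a duplicated
        covariate).
    ConvergenceError
        If the optimiser fails to converge.
    """
    if perg_parameter not in PERG_COLUMNS:
        raise ValueError(f"perg_parameter must be one of {sorted(PERG_COLUMNS)}")
    if covariates is None:
        covariates = ("age_years", "arnflt_um", PERG_COLUMNS[perg_parameter])
    required = set(covariates) | {outcome, "subject_id"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort is missing columns: {sorted(missing)}")
    if cohort[list(required)].isna().any().any():
        raise ValueError("outcome and covariates must be complete (no NaNs)")
    if cohort["subject_id"].nunique() < 2:
        raise FitError("at least 2 subjects are required")

    exog = np.column_stack(
        [np.ones(len(cohort))] + [cohort[c].to_numpy(float) for c in covariates]
    )
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise SingularDesignError(
            f"fixed-effects design with covariates {tuple(covariates)} is singular"
        )
    endog = cohort[outcome].to_numpy(float)

    model = sm.MixedLM(endog, exog, groups=cohort["subject_id"].to_numpy())
    with warnings.catch_warnings():
        # boundary fits (zero random-effect variance) warn but are valid
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=reml)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
            raise FitError(f"mixed-model estimation failed: {exc}") from exc
    if not res.converged:
        # A noise-free outcome (exact affine interpolation) drives both
        # variance components to the boundary and the optimiser flags
        # non-convergence even though the fixed effects are exact; accept
        # such perfect fits, raise otherwise.
        resid = endog - exog @ np.asarray(res.fe_params, dtype=float)
        scale = max(float(np.std(endog)), 1.0)
        if float(np.max(np.abs(resid))) > 1e-8 * scale:
            raise ConvergenceError(
                "mixed-model fit did not converge; optimiser summary:\n"
                f"{res.summary()}"
            )

    names = ["intercept", *covariates]
    params = {k: float(v) for k, v in zip(names, np.asarray(res.fe_params))}
    se = {k: float(v) for k, v in zip(names, np.asarray(res.bse_fe))}
    pvals = {k: float(v) for k, v in zip(names, np.asarray(res.pvalues)[: len(names)])}
    return LinearRGCModel(
        perg_parameter=perg_parameter,
        intercept=params["intercept"],
        coef_age=params.get("age_years", 0.0),
        coef_arnflt=params.get("arnflt_um", 0.0),
        coef_perg=params.get(PERG_COLUMNS[perg_parameter], 0.0),
        se=se,
        p_values=pvals,
        var_subject=float(np.asarray(res.cov_re)[0, 0]),
        var_resid=float(res.scale),
    )


# ---------------------------------------------------------------------------
# Splits and cross-validation
# ---------------------------------------------------------------------------

def eye_ids(cohort: pd.DataFrame) -> pd.Series:
    """Unique per-eye identifier ``subject_id:eye``."""
    return cohort["subject_id"].astype(str) + ":" + cohort["eye"].astype(str)


@dataclass(frozen=True)
class SplitSpec:
    """A reproducible training/validation partition of analysis units."""

    training_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    unit: str = "eye"
    fraction: float = 0.6
    seed: int | None = None

    def __post_init__(self) -> None:
        if set(self.training_ids) & set(self.validation_ids):
            raise ValueError("training and validation sets overlap")

    def _unit_series(self, cohort: pd.DataFrame) -> pd.Series:
        return eye_ids(cohort) if self.unit == "eye" else cohort["subject_id"].astype(str)

    def training_mask(self, cohort: pd.DataFrame) -> np.ndarray:
        return self._unit_series(cohort).isin(self.training_ids).to_numpy()

    def validation_mask(self, cohort: pd.DataFrame) -> np.ndarray:
        return self._unit_series(cohort).isin(self.validation_ids).to_numpy()


def split_cohort(
    cohort: pd.DataFrame,
    fraction: float = 0.6,
    seed: int | None = None,
    unit: str = "eye",
) -> SplitSpec:
    """Randomly partition eyes (or subjects) into training and validation.

    ``fraction`` is the proportion of units assigned to training (0.6 on a
    50-eye cohort gives the 30/20 split used to derive the bundled models);
    ``fraction = 1`` degenerates to all-training.  Identical seeds give
    identical partitions.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if unit not in ("eye", "subject"):
        raise ValueError("unit must be 'eye' or 'subject'")
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    units = sorted(
        (eye_ids(cohort) if unit == "eye" else cohort["subject_id"].astype(str)).unique()
    )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(units))
    n_train = int(round_half_away(fraction * len(units)))
    train = tuple(sorted(units[i] for i in order[:n_train]))
    valid = tuple(sorted(units[i] for i in order[n_train:]))
    return SplitSpec(train, valid, unit=unit, fraction=fraction, seed=seed)


def cross_validate(
    model: LinearRGCModel,
    validation_records: pd.DataFrame,
    outcome: str = "ergc_csfi",
) -> float:
    """Squared Pearson correlation between predictions and the outcome."""
    if len(validation_records) == 0:
        raise ValueError("validation set is empty")
    preds = model.predict_frame(validation_records)
    y = validation_records[outcome].to_numpy(float)
    if np.std(preds) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero-variance predictions or outcomes")
    r = float(np.corrcoef(preds, y)[0, 1])
    return r * r


# ---------------------------------------------------------------------------
# Loss accounting
# ---------------------------------------------------------------------------

def proportional_loss(
    reference_mean: float, group_mean: float, rounded: bool = True
) -> float:
    """Percent loss of a measure relative to the healthy reference mean.

    ``100*(reference - group)/reference``; reported values are rounded to
    integer percent with halves away from zero (set ``rounded=False`` for the
    raw value).
    """
    if not (reference_mean > 0):
        raise ValueError("reference_mean must be positive")
    pct = 100.0 * (reference_mean - group_mean) / reference_mean
    return round_half_away(pct) if rounded else pct


def annual_loss_rate(
    model: LinearRGCModel, reference_mean: float, rounded: bool = True
) -> float:
    """Model-implied age-related RGC loss, percent of the reference per year.

    ``100*|coef_age|/reference_mean``, reported to two decimals.
    """
    if not (reference_mean > 0):
        raise ValueError("reference_mean must be positive")
    rate = 100.0 * abs(model.coef_age) / reference_mean
    return round_half_away(rate, 2) if rounded else rate


@dataclass(frozen=True)
class LossSummary:
    """Percent loss of one measure in one group relative to healthy eyes."""

    reference_mean: float
    group_mean: float
    percent_loss: float = dc_field(init=False)
    percent_loss_raw: float = dc_field(init=False)

    def __post_init__(self) -> None:
        raw = proportional_loss(self.reference_mean, self.group_mean, rounded=False)
        object.__setattr__(self, "percent_loss_raw", raw)
        object.__setattr__(self, "percent_loss", round_half_away(raw))


def loss_summary(reference_mean: float, group_mean: float) -> LossSummary:
    return LossSummary(reference_mean=reference_mean, group_mean=group_mean)
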