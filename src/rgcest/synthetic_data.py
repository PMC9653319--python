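"""Synthetic bilateral glaucoma cohorts with realistic inter-eye structure.

No raw structure-function cohort of this kind is publicly deposited, so the
pipeline is exercised on simulated cohorts that reproduce the statistical
shape of a small clinical glaucoma study: three diagnostic groups — healthy,
glaucoma suspect (GS) and preperimetric glaucoma (PPG) eyes — with bilateral
eyes per subject, a shared subject age, within-subject inter-eye correlation
in every ocular measurement, and a small fraction of "discordant" subjects
whose two eyes fall in adjacent diagnostic groups.

Group marginals default to the reference cohort summary (means ± SD per
group for age, IOP, 24-2 MD, ARNFLT, Mag, MagD and the CSFI RGC estimate);
draws are truncated to physiologic bounds.  Inter-eye correlation ``ρ`` is
induced per measurement by mixing a subject-level and an eye-level standard
normal deviate with weights ``√ρ`` and ``√(1−ρ)``.

A latent "true" RGC count is generated for every eye from a configurable
linear outcome model (age, ARNFLT, PERG amplitude) plus subject- and
eye-level Gaussian noise, so that mixed-model fits on generated cohorts have
a known ground truth to recover.

:func:`generate_visual_field` supplies 24-2 sensitivity grids at a requested
mean deviation for exercising the perimetric arm of the CSFI; its normative
surface (a linear sensitivity decline with eccentricity) is a deliberately
simple stand-in for a real normative database.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .csfi import VisualField24_2, grid_24_2
from .linear_models import PERG_COLUMNS, LinearRGCModel, builtin_models

__all__ = [
    "GROUP_ORDER",
    "GroupProfile",
    "DEFAULT_PROFILES",
    "SyntheticConfig",
    "PHYSIO_BOUNDS",
    "COHORT_COLUMNS",
    "generate_cohort",
    "generate_visual_field",
]

GROUP_ORDER: tuple[str, ...] = ("healthy", "GS", "PPG")

#: Physiologic validity bounds per measurement column.  Generated values are
#: truncated to the measurement bounds (ARNFLT, Mag, MagD, MD, the latent
#: count); age and IOP are validated but drawn untruncated so the configured
#: group means are preserved.
PHYSIO_BOUNDS: dict[str, tuple[float, float]] = {
    "age_years": (0.0, 120.0),
    "iop_mmhg": (0.0, 80.0),
    "md_db": (-35.0, 3.0),
    "arnflt_um": (40.0, 130.0),
    "mag_uv": (0.0, np.inf),
    "magd_uv": (0.0, np.inf),
    "ergc_csfi": (1.0, np.inf),
}

_TRUNCATED = ("md_db", "arnflt_um", "mag_uv", "magd_uv", "ergc_csfi")

COHORT_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "eye",
    "group",
    "age_years",
    "iop_mmhg",
    "md_db",
    "arnflt_um",
    "mag_uv",
    "magd_uv",
    "latent_true_rgc",
    "ergc_csfi",
)


@dataclass(frozen=True)
class GroupProfile:
    """Marginal mean ± SD of each measurement for one diagnostic group."""

    label: str
    age_years: tuple[float, float]
    iop_mmhg: tuple[float, float]
    md_db: tuple[float, float]
    arnflt_um: tuple[float, float]
    mag_uv: tuple[float, float]
    magd_uv: tuple[float, float]
    ergc_csfi: tuple[float, float]

    def __post_init__(self) -> None:
        for name in (
            "age_years",
            "iop_mmhg",
            "md_db",
            "arnflt_um",
            "mag_uv",
            "magd_uv",
            "ergc_csfi",
        ):
            mean, sd = getattr(self, name)
            if not sd > 0:
                raise ValueError(f"{self.label}.{name}: SD must be positive, got {sd}")

    def mean(self, name: str) -> float:
        return getattr(self, name)[0]

    def sd(self, name: str) -> float:
        return getattr(self, name)[1]


#: Reference cohort summary used as simulation defaults (healthy / GS / PPG).
DEFAULT_PROFILES: dict[str, GroupProfile] = {
    "healthy": GroupProfile(
        label="healthy",
        age_years=(49.0, 12.0),
        iop_mmhg=(17.13, 3.85),
        md_db=(0.10, 1.06),
        arnflt_um=(96.80, 7.95),
        mag_uv=(1.95, 0.64),
        magd_uv=(1.72, 1.06),
        ergc_csfi=(1_076_635.0, 127_284.0),
    ),
    "GS": GroupProfile(
        label="GS",
        age_years=(50.0, 19.0),
        iop_mmhg=(17.70, 4.14),
        md_db=(-0.45, 0.94),
        arnflt_um=(85.00, 5.75),
        mag_uv=(1.35, 0.32),
        magd_uv=(1.09, 0.34),
        ergc_csfi=(912_667.0, 127_284.0),
    ),
    "PPG": GroupProfile(
        label="PPG",
        age_years=(73.0, 16.0),
        iop_mmhg=(16.80, 3.12),
        md_db=(-1.06, 1.72),
        arnflt_um=(79.20, 5.35),
        mag_uv=(1.25, 0.28),
        magd_uv=(0.79, 0.67),
        ergc_csfi=(702_679.0, 103_847.0),
    ),
}

_EYE_MEASURES = ("iop_mmhg", "md_db", "arnflt_um", "mag_uv", "magd_uv")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    Defaults emulate the reference study: 15/5/5 subjects per group (30/10/10
    eyes), inter-eye correlation 0.6, 20% of subjects discordant (one eye in
    an adjacent group, as 5 of the study's 25 subjects were), outcome
    generated from the bundled Mag model with subject-level SD 50,000 and
    eye-level SD 40,000 RGCs.
    """

    n_subjects: Mapping[str, int] = field(
        default_factory=lambda: {"healthy": 15, "GS": 5, "PPG": 5}
    )
    inter_eye_correlation: float = 0.6
    fraction_discordant: float = 0.2
    seed: int | None = None
    outcome_model: LinearRGCModel | None = None  # default: bundled Mag model
    sd_subject: float = 50_000.0
    sd_eye: float = 40_000.0
    outcome: str = "latent"  # "latent": ergc_csfi = latent count; "profile": marginal draw
    profiles: Mapping[str, GroupProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )

    def __post_init__(self) -> None:
        if not 0 <= self.inter_eye_correlation < 1:
            raise ValueError("inter_eye_correlation must be in [0, 1)")
        if not 0 <= self.fraction_discordant <= 1:
            raise ValueError("fraction_discordant must be in [0, 1]")
        if any(n <= 0 for n in self.n_subjects.values()) or not self.n_subjects:
            raise ValueError("n_subjects must be positive per group")
        unknown = set(self.n_subjects) - set(GROUP_ORDER)
        if unknown:
            raise ValueError(f"unknown groups: {sorted(unknown)}")
        if self.outcome not in ("latent", "profile"):
            raise ValueError("outcome must be 'latent' or 'profile'")
        if self.sd_subject < 0 or self.sd_eye < 0:
            raise ValueError("noise SDs must be non-negative")


def _truncate(name: str, value: float) -> float:
    if name not in _TRUNCATED:
        return float(value)
    lo, hi = PHYSIO_BOUNDS[name]
    return float(min(max(value, lo), hi))


def _adjacent_group(group: str, rng: np.random.Generator) -> str:
    i = GROUP_ORDER.index(group)
    if i == 0:
        return GROUP_ORDER[1]
    if i == len(GROUP_ORDER) - 1:
        return GROUP_ORDER[-2]
    return GROUP_ORDER[i + (1 if rng.random() < 0.5 else -1)]


def generate_cohort(config: SyntheticConfig | None = None) -> pd.DataFrame:
    """Generate a bilateral cohort, one row per eye.

    Each subject gets a primary diagnostic group, a shared age drawn from
    that group's profile, and two eyes (OD, OS).  For every eye-level
    measurement ``X`` with group mean μ and SD σ the value is
    ``μ + σ(√ρ·z_subject + √(1−ρ)·z_eye)``, which gives the two eyes of a
    subject correlation ρ while preserving the group marginal; values are
    then truncated to physiologic bounds.  Discordant subjects have one eye
    re-drawn under an adjacent group's profile (with that group's label).

    The latent true RGC count is the outcome model's prediction for the
    eye's covariates plus subject- and eye-level Gaussian noise; with
    ``outcome="latent"`` (default) it also populates ``ergc_csfi``, so
    fitted models have a known generating truth.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    model = config.outcome_model or builtin_models()[0]
    perg_col = PERG_COLUMNS[model.perg_parameter]

    rows: list[dict] = []
    sid = 0
    for group in GROUP_ORDER:
        n = config.n_subjects.get(group, 0)
        for _ in range(n):
            sid += 1
            subject_id = f"S{sid:04d}"
            prof = config.profiles[group]
            age = _truncate(
                "age_years", prof.mean("age_years") + prof.sd("age_years") * rng.standard_normal()
            )
            discordant = rng.random() < config.fraction_discordant
            odd_eye = rng.integers(2) if discordant else -1
            subj_z = {m: rng.standard_normal() for m in _EYE_MEASURES}
            subj_noise = config.sd_subject * rng.standard_normal()
            rho = config.inter_eye_correlation
            w_s, w_e = np.sqrt(rho), np.sqrt(1.0 - rho)
            for i, eye in enumerate(("OD", "OS")):
                eye_group = group
                if i == odd_eye:
                    eye_group = _adjacent_group(group, rng)
                eprof = config.profiles[eye_group]
                rec = {"subject_id": subject_id, "eye": eye, "group": eye_group,
                       "age_years": age}
                for m in _EYE_MEASURES:
                    z = w_s * subj_z[m] + w_e * rng.standard_normal()
                    rec[m] = _truncate(m, eprof.mean(m) + eprof.sd(m) * z)
                latent = (
                    float(model.predict(rec["age_years"], rec["arnflt_um"], rec[perg_col]))
                    + subj_noise
                    + config.sd_eye * rng.standard_normal()
                )
                rec["latent_true_rgc"] = latent
                if config.outcome == "latent":
                    rec["ergc_csfi"] = _truncate("ergc_csfi", latent)
                else:
                    z = w_s * subj_z.setdefault("ergc_csfi", rng.standard_normal()) + (
                        w_e * rng.standard_normal()
                    )
                    rec["ergc_csfi"] = _truncate(
                        "ergc_csfi", eprof.mean("ergc_csfi") + eprof.sd("ergc_csfi") * z
                    )
                rows.append(rec)
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


# ---------------------------------------------------------------------------
# Visual-field generation
# ---------------------------------------------------------------------------

#: Synthetic normative sensitivity surface: linear decline with eccentricity
#: from 33 dB at the innermost locations (4.24 deg) to 27 dB at 27 deg.
_NORM_S0 = 33.0
_NORM_S1 = 27.0
_NORM_EC0 = float(np.hypot(3, 3))
_NORM_EC1 = 27.0
_NORM_NOISE_SD = 1.5


def _normative_surface(ec: np.ndarray) -> np.ndarray:
    slope = (_NORM_S1 - _NORM_S0) / (_NORM_EC1 - _NORM_EC0)
    return _NORM_S0 + slope * (ec - _NORM_EC0)


def generate_visual_field(
    target_md: float, seed: int | None = None, eye: str = "OD"
) -> VisualField24_2:
    """A synthetic 24-2 field whose mean deviation is ``target_md``.

    Sensitivities are the synthetic normative surface plus N(0, 1.5 dB)
    noise, shifted so that the mean deviation from the surface equals
    ``target_md``; values are clipped to the 0-50 dB instrument range and the
    achieved MD is re-checked to 0.05 dB (an unreachable target, e.g. very
    low MD forcing mass clipping at 0 dB, raises).
    """
    if not -35.0 <= target_md <= 3.0:
        raise ValueError("target_md must lie in [-35, +3] dB")
    rng = np.random.default_rng(seed)
    g = grid_24_2(eye)
    x = g["x_deg"].to_numpy(float)
    y = g["y_deg"].to_numpy(float)
    norm = _normative_surface(np.hypot(x, y))
    s = norm + rng.normal(0.0, _NORM_NOISE_SD, size=norm.size)
    s = s + (target_md - float(np.mean(s - norm)))
    s = np.clip(s, 0.0, 50.0)
    achieved = float(np.mean(s - norm))
    if abs(achieved - target_md) > 0.05:
        raise ValueError(
            f"target MD {target_md} dB unreachable after clipping "
            f"(achieved {achieved:.2f} dB)"
        )
    return VisualField24_2(x, y, s, eye=eye)


def field_mean_deviation(field: VisualField24_2) -> float:
    """MD of a field against the synthetic normative surface."""
    norm = _normative_surface(field.eccentricity_deg)
    return float(np.mean(field.sensitivity_db - norm))
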