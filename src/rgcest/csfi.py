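"""Combined structure-function index (CSFI) estimates of retinal ganglion cell count.

The CSFI (Medeiros et al., derived from the Harwerth primate/clinical model)
produces an estimated retinal ganglion cell (RGC) count for one eye from two
independent routes and blends them according to disease stage:

* ``SAPrgc`` — a functional estimate from standard automated perimetry (SAP).
  Each 24-2 test location contributes RGCs inferred from its sensitivity
  ``s`` (dB) through an eccentricity-dependent linear map between ``s`` and
  log ganglion-cell density.
* ``OCTrgc`` — a structural estimate from the average retinal nerve fiber
  layer thickness (ARNFLT, µm), converted to an axon count via an
  age-dependent axonal density and corrected for RNFL remodelling through
  the visual-field mean deviation (MD, dB).
* ``eRGC_CSFI = (1 + MD/30)·OCTrgc + (−MD/30)·SAPrgc`` — at MD = 0 dB
  (normal field) the estimate is purely structural; at MD = −30 dB it is
  purely functional.

Two formula variants are provided. ``"corrected"`` (default) uses the forms
of the originating model: slope ``m = 0.054·ec^1.32 + 0.9``, intercept
``b = −1.5·ec^1.32 − 14.8`` and axonal density ``d = −0.007·age + 1.4``.
``"as_printed"`` evaluates the arithmetic re-transcriptions that circulate in
parts of the clinical literature (``0.54·(ec·1.32)``, ``−1.5·(ec + 1.32)``,
``(−0.007 + age) + 1.4``) literally; these yield counts that are orders of
magnitude off the physiologic ~1e6 scale and are included only so the two
readings can be compared explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VARIANTS",
    "DEFAULT_VARIANT",
    "AXONS_PER_UM_RNFL",
    "BlindSpotError",
    "GridError",
    "VisualField24_2",
    "OCTTerms",
    "CSFIResult",
    "grid_24_2",
    "blind_spot_locations",
    "eccentricity",
    "sap_rgc_count",
    "oct_rgc_count",
    "combined_csfi",
    "csfi_from_field",
]

VARIANTS: tuple[str, ...] = ("corrected", "as_printed")
DEFAULT_VARIANT = "corrected"

#: Axons per µm of average RNFL thickness in the structural estimate.
AXONS_PER_UM_RNFL = 10870.0

#: 24-2 pattern half-rows: |y| offset -> tuple of |x| offsets present on both
#: sides of the vertical meridian.  The |y| = 3 rows additionally carry one
#: nasal-step point at 27 deg on the nasal side only.
_ROWS: dict[int, tuple[int, ...]] = {
    3: (3, 9, 15, 21),
    9: (3, 9, 15, 21),
    15: (3, 9, 15),
    21: (3, 9),
}

N_LOCATIONS = 52  # 54-point 24-2 pattern minus the two blind-spot points


class GridError(ValueError):
    """A visual field does not conform to the 24-2 test pattern."""


class BlindSpotError(GridError):
    """A coordinate falls on the physiologic blind spot and must be excluded."""


def _temporal_sign(eye: str) -> int:
    if eye == "OD":
        return 1
    if eye == "OS":
        return -1
    raise GridError(f"eye must be 'OD' or 'OS', got {eye!r}")


def blind_spot_locations(eye: str = "OD") -> tuple[tuple[int, int], tuple[int, int]]:
    """The two excluded blind-spot coordinates, 15 deg temporal, y = +/-3."""
    bx = 15 * _temporal_sign(eye)
    return ((bx, 3), (bx, -3))


def grid_24_2(eye: str = "OD") -> pd.DataFrame:
    """Coordinates of the 52 analysed 24-2 locations for the given eye.

    The standard 24-2 pattern has 54 points on a 6 deg lattice (odd multiples
    of 3 deg), extended to 27 deg on the nasal side of the horizontal rows and
    excluding the two points on the blind spot (15 deg temporal, y = +/-3).
    """
    nasal = -_temporal_sign(eye)
    bs = set(blind_spot_locations(eye))
    pts: list[tuple[int, int]] = []
    for ay, xs in _ROWS.items():
        for y in (ay, -ay):
            for ax in xs:
                pts.append((ax, y))
                pts.append((-ax, y))
            if ay == 3:
                pts.append((27 * nasal, y))
    pts = [p for p in pts if p not in bs]
    pts.sort(key=lambda p: (-p[1], p[0]))
    return pd.DataFrame(pts, columns=["x_deg", "y_deg"])


def eccentricity(x_deg: float, y_deg: float, eye: str = "OD") -> float:
    """Angular distance of a 24-2 test location from fixation, in degrees.

    Raises :class:`BlindSpotError` for the two excluded blind-spot points and
    :class:`GridError` for coordinates not on the 24-2 pattern of that eye.
    """
    if (x_deg, y_deg) in blind_spot_locations(eye):
        raise BlindSpotError(
            f"({x_deg}, {y_deg}) is a blind-spot location for {eye} and is "
            "excluded from the 24-2 analysis"
        )
    valid = set(map(tuple, grid_24_2(eye).to_numpy()))
    if (x_deg, y_deg) not in valid:
        raise GridError(f"({x_deg}, {y_deg}) is not a 24-2 location for {eye}")
    return math.hypot(x_deg, y_deg)


def _check_variant(variant: str) -> None:
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")


def _slope_intercept(ec: np.ndarray, variant: str) -> tuple[np.ndarray, np.ndarray]:
    """Slope m and intercept b of the sensitivity -> log RGC density map."""
    if variant == "corrected":
        p = ec**1.32
        return 0.054 * p + 0.9, -1.5 * p - 14.8
    # literal re-transcription: products/sums instead of the power law
    return 0.54 * (ec * 1.32) + 0.9, -1.5 * (ec + 1.32) - 14.8


@dataclass(frozen=True)
class VisualField24_2:
    """A 24-2 visual field: 52 analysed sensitivities with their coordinates.

    Parameters
    ----------
    x_deg, y_deg
        Signed offsets from fixation in degrees; must form exactly the 52
        analysed locations of the 24-2 pattern for ``eye``.
    sensitivity_db
        SAP sensitivity at each location, 0-50 dB.
    eye
        Laterality, ``"OD"`` (right) or ``"OS"`` (left); fixes the blind-spot
        side and the nasal-step side.
    """

    x_deg: np.ndarray
    y_deg: np.ndarray
    sensitivity_db: np.ndarray
    eye: str = "OD"

    def __post_init__(self) -> None:
        x = np.asarray(self.x_deg, dtype=float)
        y = np.asarray(self.y_deg, dtype=float)
        s = np.asarray(self.sensitivity_db, dtype=float)
        if not (x.shape == y.shape == s.shape) or x.ndim != 1:
            raise GridError("x_deg, y_deg and sensitivity_db must be equal-length 1-d arrays")
        object.__setattr__(self, "x_deg", x)
        object.__setattr__(self, "y_deg", y)
        object.__setattr__(self, "sensitivity_db", s)
        expected = set(map(tuple, grid_24_2(self.eye).to_numpy(dtype=float)))
        got = list(zip(x.tolist(), y.tolist()))
        if len(set(got)) != len(got):
            raise GridError("duplicate test-location coordinates")
        if set(got) != expected:
            raise GridError(
                f"expected the {N_LOCATIONS} analysed 24-2 locations for "
                f"{self.eye}, got {len(got)} locations not matching the pattern"
            )
        if np.any(~np.isfinite(s)) or np.any(s < 0) or np.any(s > 50):
            raise GridError("sensitivities must be finite and within [0, 50] dB")

    def __len__(self) -> int:
        return int(self.x_deg.size)

    @property
    def eccentricity_deg(self) -> np.ndarray:
        return np.hypot(self.x_deg, self.y_deg)

    @classmethod
    def uniform(cls, sensitivity_db: float, eye: str = "OD") -> "VisualField24_2":
        """A field with the same sensitivity at all 52 locations."""
        g = grid_24_2(eye)
        return cls(
            g["x_deg"].to_numpy(float),
            g["y_deg"].to_numpy(float),
            np.full(len(g), float(sensitivity_db)),
            eye=eye,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, eye: str = "OD") -> "VisualField24_2":
        """Build from a frame with columns x_deg, y_deg, sensitivity_db."""
        missing = {"x_deg", "y_deg", "sensitivity_db"} - set(df.columns)
        if missing:
            raise GridError(f"missing columns: {sorted(missing)}")
        return cls(
            df["x_deg"].to_numpy(float),
            df["y_deg"].to_numpy(float),
            df["sensitivity_db"].to_numpy(float),
            eye=eye,
        )

    @classmethod
    def from_csv(cls, path, eye: str = "OD") -> "VisualField24_2":
        return cls.from_dataframe(pd.read_csv(path), eye=eye)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_deg": self.x_deg,
                "y_deg": self.y_deg,
                "sensitivity_db": self.sensitivity_db,
            }
        )


def sap_rgc_count(
    field: VisualField24_2, variant: str = DEFAULT_VARIANT
) -> tuple[float, pd.DataFrame]:
    """SAP-derived RGC count and the per-location term table.

    For each location at eccentricity ``ec`` with sensitivity ``s``::

        m  = slope(ec)          b = intercept(ec)
        gc = ((s - 1) - b)/m + 4.7
        contribution = 10^(gc * 0.1)

    and the field total is the sum of contributions over all 52 locations.
    ``gc`` is on a 10·log10 scale, so each contribution is positive and
    strictly increasing in ``s``; sensitivities below 1 dB simply drive the
    contribution toward zero.

    Returns
    -------
    (total, terms)
        ``total`` is the SAPrgc count; ``terms`` has one row per location
        with columns ``x_deg, y_deg, sensitivity_db, ec, m, b, gc,
        contribution``.
    """
    _check_variant(variant)
    ec = field.eccentricity_deg
    s = field.sensitivity_db
    m, b = _slope_intercept(ec, variant)
    gc = ((s - 1.0) - b) / m + 4.7
    contribution = np.power(10.0, gc * 0.1)
    terms = pd.DataFrame(
        {
            "x_deg": field.x_deg,
            "y_deg": field.y_deg,
            "sensitivity_db": s,
            "ec": ec,
            "m": m,
            "b": b,
            "gc": gc,
            "contribution": contribution,
        }
    )
    return float(contribution.sum()), terms


@dataclass(frozen=True)
class OCTTerms:
    """Intermediate quantities of the structural (OCT) RGC estimate."""

    age_years: float
    arnflt_um: float
    md_db: float
    d: float  # axonal density, axons/µm²
    c: float  # remodelling correction factor
    a: float  # estimated axon count
    count: float  # OCTrgc
    variant: str = DEFAULT_VARIANT


def oct_rgc_count(
    age_years: float,
    arnflt_um: float,
    md_db: float,
    variant: str = DEFAULT_VARIANT,
) -> tuple[float, OCTTerms]:
    """OCT-derived RGC count from age, average RNFL thickness and MD.

    ::

        d = -0.007*age + 1.4          (axons/µm², declines with age)
        c = -0.26*MD + 0.12           (remodelling correction)
        a = ARNFLT * 10870 * d        (estimated axon count)
        OCTrgc = 10^((log10(a)*10 - c) * 0.1)  ==  a * 10^(-c/10)

    The ``as_printed`` variant evaluates ``d = (-0.007 + age) + 1.4``
    literally instead.
    """
    _check_variant(variant)
    if not (age_years > 0):
        raise ValueError("age_years must be positive")
    if not (arnflt_um > 0):
        raise ValueError("arnflt_um must be positive")
    if variant == "corrected":
        d = -0.007 * age_years + 1.4
    else:
        d = (-0.007 + age_years) + 1.4
    c = -0.26 * md_db + 0.12
    a = arnflt_um * AXONS_PER_UM_RNFL * d
    if not (a > 0):
        raise ValueError(f"estimated axon count is non-positive (a={a:g}); inputs invalid")
    count = 10.0 ** ((math.log10(a) * 10.0 - c) * 0.1)
    return count, OCTTerms(age_years, arnflt_um, md_db, d, c, a, count, variant)


@dataclass(frozen=True)
class CSFIResult:
    """SAP-derived, OCT-derived and combined RGC count for one eye."""

    sap_rgc: float
    oct_rgc: float
    md_db: float
    w_oct: float = field(init=False)
    w_sap: float = field(init=False)
    ergc_csfi: float = field(init=False)
    variant: str = DEFAULT_VARIANT

    def __post_init__(self) -> None:
        if not (self.sap_rgc > 0 and self.oct_rgc > 0):
            raise ValueError("both RGC counts must be positive")
        w_oct = 1.0 + self.md_db / 30.0
        w_sap = -self.md_db / 30.0
        object.__setattr__(self, "w_oct", w_oct)
        object.__setattr__(self, "w_sap", w_sap)
        object.__setattr__(
            self, "ergc_csfi", w_oct * self.oct_rgc + w_sap * self.sap_rgc
        )


def combined_csfi(
    sap_rgc: float, oct_rgc: float, md_db: float, variant: str = DEFAULT_VARIANT
) -> CSFIResult:
    """MD-weighted blend of the functional and structural counts.

    The structural weight is ``1 + MD/30`` and the functional weight
    ``-MD/30``; they sum to one for every MD, so a normal field (MD = 0)
    returns ``oct_rgc`` exactly and MD = -30 dB returns ``sap_rgc`` exactly.
    """
    _check_variant(variant)
    return CSFIResult(sap_rgc=sap_rgc, oct_rgc=oct_rgc, md_db=md_db, variant=variant)


def csfi_from_field(
    field_: VisualField24_2,
    age_years: float,
    arnflt_um: float,
    md_db: float,
    variant: str = DEFAULT_VARIANT,
) -> CSFIResult:
    """Full CSFI chain for one eye: SAPrgc, OCTrgc and their blend."""
    sap, _ = sap_rgc_count(field_, variant)
    oct_, _ = oct_rgc_count(age_years, arnflt_um, md_db, variant)
    return combined_csfi(sap, oct_, md_db, variant)
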