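"""SEC universal calibration with pullulan standards and the Mark–Houwink
equation.

Size-exclusion chromatography separates by hydrodynamic volume, which for
a polymer of molar mass ``M`` is proportional to ``[η]·M = K·M^(1+α)``
with ``(K, α)`` the Mark–Houwink constants for the polymer/eluent/
temperature combination (for pullulan in DMSO/LiBr at 80 °C:
``K = 2.424e-4 dL/g``, ``α = 0.68``).  A series of narrow pullulan
standards of known ``M`` defines the map from elution volume ``Ve`` to
``log10 K·M^(1+α)``; inverting it converts a sample's elution volume to
``M`` and then to degree of polymerization ``X = M / 162.2`` (the
anhydroglucose residue mass; chain-end water is neglected, an error under
0.2 % above DP 60).

The calibration curve is a least-squares polynomial in ``Ve`` (default
degree 3) and must be strictly decreasing over the fitted range — larger
molecules elute earlier.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, ParameterError

__all__ = [
    "MarkHouwink",
    "PullulanStandard",
    "CalibrationFit",
    "universal_ordinate",
    "fit_calibration",
    "elution_to_dp",
    "read_standards",
    "write_standards",
    "ANHYDROGLUCOSE_MASS",
]

ANHYDROGLUCOSE_MASS = 162.2  # g/mol per residue; chain-end water neglected

# commercial pullulan standard series span 342 .. 2.35e6 g/mol
PULLULAN_RANGE = (342.0, 2.35e6)


@dataclass(frozen=True)
class MarkHouwink:
    """Mark–Houwink constants: ``[η] = K·M^α`` (K in dL/g)."""

    K: float = 2.424e-4
    alpha: float = 0.68

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ParameterError(f"K must be positive, got {self.K}")
        if not (0 <= self.alpha <= 1):
            raise ParameterError(f"alpha must be in [0, 1], got {self.alpha}")


@dataclass(frozen=True)
class PullulanStandard:
    """One calibration standard: molar mass (g/mol) and elution volume (mL)."""

    molar_mass: float
    elution_volume: float

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ParameterError("molar mass must be positive")
        if self.elution_volume <= 0:
            raise ParameterError("elution volume must be positive")


@dataclass(frozen=True)
class CalibrationFit:
    """Polynomial map ``Ve -> log10(K·M^(1+α))`` with diagnostics.

    ``coefficients`` are in numpy.polynomial order (low degree first);
    ``ve_range`` is the fitted elution-volume range and ``residual_sd`` the
    root-mean-square residual of the fit.
    """

    coefficients: tuple[float, ...]
    ve_range: tuple[float, float]
    residual_sd: float
    mark_houwink: MarkHouwink

    def ordinate(self, ve: float | np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(ve, dtype=float),
                                                np.asarray(self.coefficients))


def universal_ordinate(molar_mass: float | np.ndarray, mh: MarkHouwink) -> float | np.ndarray:
    """Hydrodynamic-volume proxy ``K·M^(1+α)``.

    Proportionality constants common to standards and samples cancel in
    calibration, so the proxy itself is the calibrated ordinate.
    """
    m = np.asarray(molar_mass, dtype=float)
    if np.any(m <= 0):
        raise ParameterError("molar mass must be positive")
    out = mh.K * m ** (1.0 + mh.alpha)
    return float(out) if np.isscalar(molar_mass) else out


def fit_calibration(
    standards: Sequence[PullulanStandard],
    mh: MarkHouwink | None = None,
    degree: int = 3,
) -> CalibrationFit:
    """Least-squares polynomial calibration from pullulan standards.

    Requires at least ``degree + 1`` standards with molar mass strictly
    decreasing in elution volume; the fitted polynomial must itself be
    strictly decreasing over the data range (checked on a fine grid).

    Raises
    ------
    CalibrationError
        Too few standards, non-monotone standards, or a non-monotone fit.
    """
    mh = mh or MarkHouwink()
    if degree < 1:
        raise ParameterError("degree must be >= 1")
    if len(standards) < degree + 1:
        raise CalibrationError(
            f"need at least {degree + 1} standards for degree {degree}, "
            f"got {len(standards)}"
        )
    order = sorted(standards, key=lambda s: s.elution_volume)
    ve = np.array([s.elution_volume for s in order])
    mass = np.array([s.molar_mass for s in order])
    if np.any(np.diff(ve) <= 0):
        raise CalibrationError("duplicate elution volumes in standards")
    if np.any(np.diff(mass) >= 0):
        raise CalibrationError(
            "standards must have strictly decreasing molar mass with "
            "increasing elution volume"
        )
    y = np.log10(universal_ordinate(mass, mh))
    coeffs = np.polynomial.polynomial.polyfit(ve, y, degree)
    fitted = np.polynomial.polynomial.polyval(ve, coeffs)
    resid_sd = float(np.sqrt(np.mean((fitted - y) ** 2)))
    # monotonicity of the fitted curve over the data range
    grid = np.linspace(ve.min(), ve.max(), 512)
    vals = np.polynomial.polynomial.polyval(grid, coeffs)
    if np.any(np.diff(vals) >= 0):
        raise CalibrationError(
            "fitted calibration is not strictly decreasing over the data "
            "range; lower the degree or check the standards"
        )
    return CalibrationFit(
        coefficients=tuple(float(c) for c in coeffs),
        ve_range=(float(ve.min()), float(ve.max())),
        residual_sd=resid_sd,
        mark_houwink=mh,
    )


def elution_to_dp(
    ve: float | np.ndarray,
    fit: CalibrationFit,
    mh: MarkHouwink | None = None,
    *,
    monomer_mass: float = ANHYDROGLUCOSE_MASS,
    extrapolate: bool = False,
) -> float | np.ndarray:
    """Convert elution volume(s) to degree of polymerization.

    Inverts the calibration to molar mass, ``M = (ordinate/K)^(1/(1+α))``,
    then ``X = M / monomer_mass``.  The Mark–Houwink pair defaults to the
    one the calibration was fitted with (a single pair for standards and
    samples; its K then cancels exactly).

    Raises
    ------
    CalibrationError
        If ``ve`` lies outside the fitted range and ``extrapolate`` is off.
    """
    mh = mh or fit.mark_houwink
    v = np.asarray(ve, dtype=float)
    lo, hi = fit.ve_range
    if not extrapolate and (np.any(v < lo - 1e-12) or np.any(v > hi + 1e-12)):
        raise CalibrationError(
            f"elution volume outside calibrated range [{lo}, {hi}]; "
            "pass extrapolate=True to override"
        )
    log_ord = fit.ordinate(v)
    mass = (10.0**log_ord / mh.K) ** (1.0 / (1.0 + mh.alpha))
    dp = mass / monomer_mass
    return float(dp) if np.isscalar(ve) else dp


def write_standards(standards: Sequence[PullulanStandard], path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame(
        {
            "molar_mass": [s.molar_mass for s in standards],
            "elution_volume_mL": [s.elution_volume for s in standards],
        }
    ).to_csv(path, sep=sep, index=False)


def read_standards(path: str | Path, sep: str = "\t") -> list[PullulanStandard]:
    df = pd.read_csv(path, sep=sep)
    cols = list(df.columns[:2])
    if cols != ["molar_mass", "elution_volume_mL"]:
        raise ParameterError(
            f"standards file must have columns molar_mass,elution_volume_mL; got {cols}"
        )
    return [
        PullulanStandard(float(m), float(v))
        for m, v in zip(df["molar_mass"], df["elution_volume_mL"])
    ]
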