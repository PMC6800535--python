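"""Standard-curve fitting of dilution series and extinction-coefficient conversion.

Workflow: absorbance vs concentration is fit by ordinary least squares
(slope ``a``, intercept ``b``); the slope over the optical path length gives
the extinction coefficient in the concentration unit of the series; a final
unit conversion yields the molar coefficient.  The intercept is estimated
(not forced to zero) and reported as a QC diagnostic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DegenerateDesignError

#: Absorbances above this default are excluded from fits (linearity range).
DEFAULT_MAX_ABSORBANCE_AU = 2.5

#: Optical path length of a filled UV microplate well, cm.
MICROPLATE_PATH_CM = 0.56


class ConcUnit(str, enum.Enum):
    """Concentration unit of a dilution series."""

    MASS_PER_VOLUME = "mass_per_volume"  # mg/mL; molar conversion needs MW
    MILLIMOLAR = "millimolar"


@dataclass
class DilutionSeries:
    """Replicate (concentration, absorbance) table at one wavelength."""

    wavelength_nm: float
    data: pd.DataFrame  # columns: conc, replicate, absorbance
    conc_unit: ConcUnit = ConcUnit.MASS_PER_VOLUME

    def __post_init__(self) -> None:
        required = {"conc", "replicate", "absorbance"}
        if not required.issubset(self.data.columns):
            raise ConfigurationError(
                f"dilution table needs columns {sorted(required)}, "
                f"got {list(self.data.columns)}"
            )
        if self.data["conc"].nunique() < 3:
            raise ConfigurationError("need at least 3 distinct concentrations")
        if (self.data["absorbance"] < -0.05).any():
            raise ConfigurationError(
                "absorbance below -0.05 AU; check blanking"
            )


@dataclass(frozen=True)
class StandardCurve:
    """OLS line Y = a X + b over all replicate points."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    stderr_slope: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ConfigurationError("standard curve needs >= 3 points")
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ConfigurationError("r_squared outside [0, 1]")


@dataclass(frozen=True)
class ExtinctionSet:
    """Molar extinction coefficients at the drug and antibody wavelengths.

    ``eAb*`` are antibody coefficients at 252/280 nm, ``eD*`` the drug's,
    all in M^-1 cm^-1.
    """

    eAb252: float
    eAb280: float
    eD252: float
    eD280: float

    def __post_init__(self) -> None:
        for name in ("eAb252", "eAb280", "eD252", "eD280"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"extinction {name} must be positive")

    def to_dict(self) -> dict:
        return {
            "eAb252": self.eAb252,
            "eAb280": self.eAb280,
            "eD252": self.eD252,
            "eD280": self.eD280,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExtinctionSet":
        return cls(
            eAb252=float(d["eAb252"]),
            eAb280=float(d["eAb280"]),
            eD252=float(d["eD252"]),
            eD280=float(d["eD280"]),
        )


def fit_standard_curve(
    series: DilutionSeries,
    max_absorbance: float = DEFAULT_MAX_ABSORBANCE_AU,
) -> StandardCurve:
    """Fit Y = a X + b by OLS over all replicate points.

    Points above ``max_absorbance`` are excluded (outside the detector's
    linear range).  Replicates enter as independent points.
    """
    table = series.data[series.data["absorbance"] <= max_absorbance]
    x = table["conc"].to_numpy(dtype=float)
    y = table["absorbance"].to_numpy(dtype=float)
    if len(x) < 3 or np.unique(x).size < 2:
        raise DegenerateDesignError(
            "cannot fit a line: fewer than 2 distinct concentrations remain "
            "after linear-range filtering"
        )
    res = stats.linregress(x, y)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        n_points=len(x),
        stderr_slope=float(res.stderr),
    )


def slope_to_extinction(curve: StandardCurve, path_cm: float) -> float:
    """Extinction coefficient (per concentration unit) from the fitted slope.

    epsilon = slope / path, i.e. the Beer-Lambert proportionality once the
    path length is divided out.
    """
    if path_cm <= 0:
        raise ConfigurationError("path_cm must be positive")
    return curve.slope / path_cm


def to_molar(
    extinction: float,
    conc_unit: Union[ConcUnit, str],
    mw_Da: Optional[float] = None,
) -> float:
    """Convert an extinction coefficient to M^-1 cm^-1.

    mass-per-volume (0.1% solution, mg/mL) coefficients scale by the molar
    mass; millimolar coefficients scale by 1000.
    """
    unit = ConcUnit(conc_unit)
    if unit is ConcUnit.MASS_PER_VOLUME:
        if mw_Da is None:
            raise ConfigurationError(
                "mw_Da is required to convert a mass-per-volume extinction"
            )
        return extinction * mw_Da
    return extinction * 1000.0


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

_CONC_COLUMNS = {"conc_mg_ml": ConcUnit.MASS_PER_VOLUME, "conc_mM": ConcUnit.MILLIMOLAR}


def read_dilution_csv(path: Union[str, Path], wavelength_nm: float) -> DilutionSeries:
    """Read a dilution series CSV (conc_mg_ml or conc_mM, replicate, absorbance)."""
    df = pd.read_csv(path)
    for col, unit in _CONC_COLUMNS.items():
        if col in df.columns:
            table = df.rename(columns={col: "conc"})[
                ["conc", "replicate", "absorbance"]
            ]
            return DilutionSeries(wavelength_nm, table, unit)
    raise ConfigurationError(
        f"no concentration column among {sorted(_CONC_COLUMNS)} in {path}"
    )


def write_dilution_csv(series: DilutionSeries, path: Union[str, Path]) -> None:
    col = {v: k for k, v in _CONC_COLUMNS.items()}[series.conc_unit]
    out = series.data.rename(columns={"conc": col})
    out.to_csv(path, index=False)


def write_fit_report(
    rows: list[tuple[float, StandardCurve, float]], path: Union[str, Path]
) -> None:
    """Write (wavelength, fitted curve, molar epsilon) rows as CSV."""
    df = pd.DataFrame(
        [
            {
                "wavelength_nm": wl,
                "slope": c.slope,
                "intercept": c.intercept,
                "r2": c.r_squared,
                "epsilon_molar": eps,
            }
            for wl, c, eps in rows
        ]
    )
    df.to_csv(path, index=False)
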