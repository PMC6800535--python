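"""Two-wavelength UV determination of the drug-to-antibody ratio.

Under absorbance additivity the conjugate's absorbance at each wavelength is
the antibody term plus ``dar`` drug terms.  Writing R = A(drug λmax)/A(280),
the ratio map

    R(dar) = (eAb252 + dar * eD252) / (eAb280 + dar * eD280)

is inverted in closed form:

    dar = (eAb252 - R * eAb280) / (R * eD280 - eD252)

The inversion is exact on the physical branch; the unit tests verify the
round trip rather than assuming it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SingularRatioError, SpectrumRangeError
from .extinction import MICROPLATE_PATH_CM, ExtinctionSet

DRUG_WAVELENGTH_NM = 252.0
ANTIBODY_WAVELENGTH_NM = 280.0

#: Computed DARs below this are flagged (R below the unconjugated baseline).
_NEGATIVE_DAR_FLAG = -0.05


@dataclass
class UVSpectrum:
    """Ordered (wavelength, absorbance) pairs for one sample."""

    wavelength_nm: np.ndarray
    absorbance_AU: np.ndarray
    sample_id: str = ""
    path_cm: float = MICROPLATE_PATH_CM

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.absorbance_AU = np.asarray(self.absorbance_AU, dtype=float)
        if self.wavelength_nm.shape != self.absorbance_AU.shape:
            raise ConfigurationError("wavelength and absorbance lengths differ")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ConfigurationError("wavelengths must be strictly increasing")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelength_nm[0]), float(self.wavelength_nm[-1])


@dataclass(frozen=True)
class UVDarResult:
    """Outcome of a UV DAR determination."""

    R: float
    dar: float
    extinctions: ExtinctionSet
    warning: Optional[str] = None
    sample_id: str = ""

    @property
    def dar_display(self) -> float:
        """One-decimal display value; full precision stays in ``dar``."""
        return round(self.dar, 1)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "method": "uv",
            "R": self.R,
            "dar": self.dar,
            "dar_display": self.dar_display,
            "extinctions": self.extinctions.to_dict(),
            "warning": self.warning,
        }

    def write_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def absorbance_at(
    spectrum: UVSpectrum, wavelength_nm: float, window_nm: float = 0.0
) -> float:
    """Absorbance at a wavelength.

    ``window_nm == 0``: the exact grid point if present, else linear
    interpolation between neighbours.  ``window_nm > 0``: mean over points
    within +/- window/2, falling back to interpolation if none land inside.
    """
    lo, hi = spectrum.span
    if not (lo <= wavelength_nm <= hi):
        raise SpectrumRangeError(
            f"{wavelength_nm} nm outside recorded span [{lo}, {hi}] nm"
        )
    wl, ab = spectrum.wavelength_nm, spectrum.absorbance_AU
    if window_nm > 0:
        mask = np.abs(wl - wavelength_nm) <= window_nm / 2
        if mask.any():
            return float(ab[mask].mean())
    return float(np.interp(wavelength_nm, wl, ab))


def forward_ratio(dar: float, ext: ExtinctionSet) -> float:
    """The forward absorbance-ratio map R(dar); the inverse's test oracle."""
    return (ext.eAb252 + dar * ext.eD252) / (ext.eAb280 + dar * ext.eD280)


def dar_from_uv(R: float, ext: ExtinctionSet, sample_id: str = "") -> UVDarResult:
    """Invert the absorbance ratio into moles of drug per mole of antibody."""
    if R <= 0:
        raise ConfigurationError(f"absorbance ratio R must be positive, got {R}")
    denom = R * ext.eD280 - ext.eD252
    if abs(denom) < 1e-9:
        raise SingularRatioError(
            f"R={R} sits on the pole of the DAR inversion (denominator ~ 0)"
        )
    dar = (ext.eAb252 - R * ext.eAb280) / denom
    warning = None
    if dar < _NEGATIVE_DAR_FLAG:
        warning = "R below unconjugated baseline"
        warnings.warn(warning, stacklevel=2)
    return UVDarResult(R=R, dar=dar, extinctions=ext, warning=warning,
                       sample_id=sample_id)


def dar_from_uv_spectrum(
    spectrum: UVSpectrum,
    ext: ExtinctionSet,
    window_nm: float = 0.0,
) -> UVDarResult:
    """Read A252 and A280 off a spectrum and invert their ratio."""
    a_drug = absorbance_at(spectrum, DRUG_WAVELENGTH_NM, window_nm)
    a_ab = absorbance_at(spectrum, ANTIBODY_WAVELENGTH_NM, window_nm)
    return dar_from_uv(a_drug / a_ab, ext, sample_id=spectrum.sample_id)


def read_uv_csv(
    path: Union[str, Path], sample_id: str = "", path_cm: float = 0.56
) -> UVSpectrum:
    """Read a UV spectrum CSV with header wavelength_nm,absorbance."""
    df = pd.read_csv(path)
    if not {"wavelength_nm", "absorbance"}.issubset(df.columns):
        raise ConfigurationError(
            f"UV CSV {path} needs columns wavelength_nm,absorbance"
        )
    sid = sample_id or Path(path).stem
    return UVSpectrum(
        df["wavelength_nm"].to_numpy(),
        df["absorbance"].to_numpy(),
        sample_id=sid,
        path_cm=path_cm,
    )


def write_uv_csv(spectrum: UVSpectrum, path: Union[str, Path]) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelength_nm, "absorbance": spectrum.absorbance_AU}
    ).to_csv(path, index=False)
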