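"""Synthetic dilution series, UV spectra, and linear-mode intact-mass spectra.

Every generator is a pure function of its arguments and seed, so downstream
fitting and DAR stages are testable without instrument data.  The mass model
mirrors the analysis: species ``k`` (an antibody carrying ``k`` drug-linkers)
sits at the antibody mass plus ``k`` per-drug mass additions, with a
truncated drug-load distribution over ``k``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .chem import ConjugateDesign, per_drug_mass_addition
from .errors import ConfigurationError
from .extinction import ConcUnit, DilutionSeries, ExtinctionSet
from .ms_dar import PROTON_MASS_DA, MassSpectrum
from .uv_dar import UVSpectrum

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

# Fixed UV basis bands (nm); only the 252/280 nm values are contract-bearing.
_AB_BAND_CENTER, _AB_BAND_SIGMA = 280.0, 15.0
_DRUG_BAND_CENTER, _DRUG_BAND_SIGMA = 252.0, 18.0


@dataclass(frozen=True)
class LoadDistribution:
    """Distribution of the number of drugs per antibody, truncated at max_load.

    Truncation renormalizes the retained probabilities (no lumping at the
    bound), so the truncated mean is a plain weighted sum over k.
    """

    kind: str = "poisson"  # poisson | binomial | fixed
    mean_load: float = 3.5
    max_load: int = 8
    site_count: Optional[int] = None
    per_site_prob: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("poisson", "binomial", "fixed"):
            raise ConfigurationError(f"unknown load distribution kind {self.kind!r}")
        if self.max_load < 0:
            raise ConfigurationError("max_load must be non-negative")
        if not (0 <= self.mean_load <= self.max_load) and self.kind != "binomial":
            raise ConfigurationError("require 0 <= mean_load <= max_load")
        if self.kind == "binomial" and (
            self.site_count is None or self.per_site_prob is None
        ):
            raise ConfigurationError(
                "binomial load needs site_count and per_site_prob"
            )
        if self.kind == "fixed" and abs(self.mean_load - round(self.mean_load)) > 1e-9:
            raise ConfigurationError("fixed load requires an integer mean_load")

    def probabilities(self) -> np.ndarray:
        """P(k) for k = 0..max_load, renormalized to sum to 1."""
        k = np.arange(self.max_load + 1)
        if self.kind == "poisson":
            p = stats.poisson.pmf(k, self.mean_load)
        elif self.kind == "binomial":
            p = stats.binom.pmf(k, self.site_count, self.per_site_prob)
        else:
            p = np.zeros(self.max_load + 1)
            p[int(round(self.mean_load))] = 1.0
        total = p.sum()
        if total <= 0:
            raise ConfigurationError("load distribution has zero mass on 0..max_load")
        return p / total

    def truncated_mean(self) -> float:
        p = self.probabilities()
        return float(np.sum(np.arange(self.max_load + 1) * p))


@dataclass(frozen=True)
class InstrumentModel:
    """Linear-mode acquisition model: resolution, baseline, noise, grid."""

    resolution: float = 300.0  # m / FWHM(m)
    baseline_level: float = 0.0
    baseline_slope: float = 0.0  # intensity per Da
    noise_sd: float = 0.0
    mz_step: float = 2.0
    charge: int = 1
    proton_mass_Da: float = PROTON_MASS_DA

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ConfigurationError("resolution must be positive")
        if self.mz_step <= 0:
            raise ConfigurationError("mz_step must be positive")
        if self.charge < 1:
            raise ConfigurationError("charge must be >= 1")


def gen_dilution_series(
    epsilon_molar: float,
    mw_Da: float,
    path_cm: float,
    start_conc: float = 1.0,
    n_dilutions: int = 8,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    wavelength_nm: float = 280.0,
) -> DilutionSeries:
    """Two-fold serial dilution with Beer-Lambert absorbance and replicate noise.

    Concentrations are ``start_conc / 2**i`` in mg/mL; absorbance is
    ``(epsilon_molar / mw_Da) * conc * path_cm`` plus Gaussian noise.
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be non-negative")
    if min(epsilon_molar, mw_Da, path_cm, start_conc) <= 0:
        raise ConfigurationError("physical arguments must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_dilutions):
        conc = start_conc / 2.0**i
        clean = (epsilon_molar / mw_Da) * conc * path_cm
        for rep in range(n_replicates):
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append((conc, rep, clean + noise))
    table = pd.DataFrame(rows, columns=["conc", "replicate", "absorbance"])
    return DilutionSeries(wavelength_nm, table, ConcUnit.MASS_PER_VOLUME)


def _band(center: float, sigma: float, wavelengths: np.ndarray) -> np.ndarray:
    return np.exp(-((wavelengths - center) ** 2) / (2.0 * sigma**2))


def _species_curve(
    e252: float, e280: float, wavelengths: np.ndarray
) -> np.ndarray:
    """Two-band extinction curve pinned to the given 252/280 nm values.

    The amplitudes of the fixed antibody and drug bands are solved from a
    2x2 linear system so the curve passes exactly through (252, e252) and
    (280, e280).
    """
    anchors = np.array([252.0, 280.0])
    basis_at_anchors = np.column_stack(
        [
            _band(_AB_BAND_CENTER, _AB_BAND_SIGMA, anchors),
            _band(_DRUG_BAND_CENTER, _DRUG_BAND_SIGMA, anchors),
        ]
    )
    amps = np.linalg.solve(basis_at_anchors, np.array([e252, e280]))
    return amps[0] * _band(_AB_BAND_CENTER, _AB_BAND_SIGMA, wavelengths) + amps[
        1
    ] * _band(_DRUG_BAND_CENTER, _DRUG_BAND_SIGMA, wavelengths)


def gen_uv_spectrum(
    extinctions: ExtinctionSet,
    dar_true: float,
    ab_conc_molar: float,
    path_cm: float,
    wavelengths: Optional[Sequence[float]] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_id: str = "synthetic-uv",
) -> UVSpectrum:
    """Additive antibody + drug UV spectrum for a chosen true DAR.

    A(lambda) = [eAb(lambda) + dar_true * eD(lambda)] * C * L + noise, with
    species curves pinned to the extinction set at 252 and 280 nm.
    """
    if dar_true < 0:
        raise ConfigurationError("dar_true must be non-negative")
    wl = (
        np.arange(200.0, 361.0, 1.0)
        if wavelengths is None
        else np.asarray(wavelengths, dtype=float)
    )
    if wl.min() < 200.0 or wl.max() > 400.0:
        raise ConfigurationError("wavelengths must lie within 200-400 nm")
    e_ab = _species_curve(extinctions.eAb252, extinctions.eAb280, wl)
    e_d = _species_curve(extinctions.eD252, extinctions.eD280, wl)
    absorbance = (e_ab + dar_true * e_d) * ab_conc_molar * path_cm
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        absorbance = absorbance + rng.normal(0.0, noise_sd, size=wl.shape)
    return UVSpectrum(wl, absorbance, sample_id=sample_id, path_cm=path_cm)


def gen_maldi_spectrum(
    design: ConjugateDesign,
    load: LoadDistribution,
    instrument: InstrumentModel = InstrumentModel(),
    mz_range: tuple[float, float] = (140_000.0, 162_000.0),
    seed: int = 0,
    total_area: float = 1e6,
) -> MassSpectrum:
    """Low-resolution single-charge intact-mass spectrum of a conjugate ensemble.

    Species k contributes a Gaussian at (M_k + z*mp)/z with
    FWHM = center / resolution and area proportional to P(k); baseline and
    Gaussian noise are added on a uniform m/z grid.  Ground truth (true mean
    load after truncation, species masses) is stored in ``metadata``.
    """
    lo, hi = mz_range
    if hi <= lo:
        raise ConfigurationError("mz_range must be non-empty")
    probs = load.probabilities()
    delta = per_drug_mass_addition(design)
    ab_mass = design.antibody.reference_mass_Da
    z, mp = instrument.charge, instrument.proton_mass_Da
    centers = (ab_mass + np.arange(load.max_load + 1) * delta + z * mp) / z
    fwhm = centers / instrument.resolution
    present = probs > 1e-12  # zero-weight species need no grid coverage
    if ((centers - 5 * fwhm)[present].min() < lo
            or (centers + 5 * fwhm)[present].max() > hi):
        raise ConfigurationError(
            "mz_range must span all species peaks +/- 5 FWHM"
        )
    mz = np.arange(lo, hi + instrument.mz_step / 2, instrument.mz_step)
    sigma = fwhm / _FWHM_PER_SIGMA
    intensity = np.zeros_like(mz)
    for p, c, s in zip(probs, centers, sigma):
        intensity += (
            total_area * p / (s * np.sqrt(2 * np.pi))
        ) * np.exp(-((mz - c) ** 2) / (2 * s**2))
    intensity += instrument.baseline_level + instrument.baseline_slope * (mz - lo)
    if instrument.noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, instrument.noise_sd, size=mz.shape)
    metadata = {
        "true_mean_load": load.truncated_mean(),
        "antibody_mass_Da": ab_mass,
        "per_drug_mass_Da": delta,
        "load_probabilities": probs.tolist(),
        "charge": z,
        "resolution": instrument.resolution,
        "seed": seed,
    }
    return MassSpectrum(mz, intensity, charge=z, metadata=metadata)


# ---------------------------------------------------------------------------
# File outputs with ground-truth sidecars
# ---------------------------------------------------------------------------

def write_with_ground_truth(
    spectrum: Union[MassSpectrum, UVSpectrum],
    path: Union[str, Path],
    ground_truth: Optional[dict] = None,
    mzml: bool = False,
) -> Path:
    """Write a simulated spectrum plus a JSON sidecar of its ground truth."""
    path = Path(path)
    if isinstance(spectrum, MassSpectrum):
        if mzml:
            spectrum.write_mzml(path)
        else:
            spectrum.write_tsv(path)
        truth = dict(spectrum.metadata)
    else:
        from .uv_dar import write_uv_csv

        write_uv_csv(spectrum, path)
        truth = {"sample_id": spectrum.sample_id, "path_cm": spectrum.path_cm}
    if ground_truth:
        truth.update(ground_truth)
    sidecar = path.with_suffix(path.suffix + ".truth.json")
    sidecar.write_text(json.dumps(truth, indent=2) + "\n")
    return sidecar
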