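"""Registry of drugs, linkers and antibodies, and conjugation mass bookkeeping.

A lysine conjugate adds, per coupled drug, the drug mass plus the linker mass
minus the N-hydroxysuccinimide leaving group that departs on antibody
coupling.  All masses are average masses in Da; isotopic fine structure and
glycoform enumeration are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .errors import ConfigurationError, UnknownLinkerError

#: Average mass of the NHS leaving group lost on lysine coupling.
NHS_LEAVING_GROUP_DA = 115.0

#: Default DM1 (mertansine) average mass, Da.
DM1_MW_DA = 738.29


@dataclass(frozen=True)
class LinkerSpec:
    """A heterobifunctional NHS-ester/maleimide crosslinker."""

    name: str
    spacer_arm_A: float
    mw_Da: float
    leaving_group_Da: float = NHS_LEAVING_GROUP_DA

    def __post_init__(self) -> None:
        if not (self.mw_Da > self.leaving_group_Da > 0):
            raise ConfigurationError(
                f"linker {self.name!r}: require mw_Da > leaving_group_Da > 0, "
                f"got mw_Da={self.mw_Da}, leaving_group_Da={self.leaving_group_Da}"
            )
        if self.spacer_arm_A <= 0:
            raise ConfigurationError(
                f"linker {self.name!r}: spacer_arm_A must be positive"
            )


@dataclass(frozen=True)
class DrugSpec:
    """A small-molecule payload with a UV absorbance maximum."""

    name: str
    mw_Da: float
    lambda_max_nm: float = 252.0

    def __post_init__(self) -> None:
        if self.mw_Da <= 0:
            raise ConfigurationError(f"drug {self.name!r}: mw_Da must be positive")
        if not (200.0 <= self.lambda_max_nm <= 400.0):
            raise ConfigurationError(
                f"drug {self.name!r}: lambda_max_nm must lie in [200, 400] nm"
            )


@dataclass(frozen=True)
class AntibodySpec:
    """A monoclonal antibody scaffold.

    ``mw_formula_Da`` is the sequence-derived mass used for molar extinction
    conversion; ``mw_measured_Da`` is the observed intact (glycosylated) mass
    used as the mass-spectrometric reference when available.
    """

    name: str
    mw_formula_Da: float
    mw_measured_Da: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mw_formula_Da <= 100_000:
            raise ConfigurationError(
                f"antibody {self.name!r}: mw_formula_Da must exceed 100 kDa"
            )
        if self.mw_measured_Da is not None and self.mw_measured_Da <= 100_000:
            raise ConfigurationError(
                f"antibody {self.name!r}: mw_measured_Da must exceed 100 kDa"
            )

    @property
    def reference_mass_Da(self) -> float:
        """Mass used as the unconjugated reference: measured if known."""
        return (
            self.mw_measured_Da
            if self.mw_measured_Da is not None
            else self.mw_formula_Da
        )


@dataclass(frozen=True)
class ConjugateDesign:
    """Antibody + drug + linker, with an optional explicit per-drug mass.

    The override exists because a published mass-addition column may round
    differently from the component masses; when set it must stay within 5 Da
    of the component-derived value.
    """

    antibody: AntibodySpec
    drug: DrugSpec
    linker: LinkerSpec
    per_drug_mass_override_Da: Optional[float] = None

    def __post_init__(self) -> None:
        if self.per_drug_mass_override_Da is not None:
            derived = mass_addition(
                self.drug.mw_Da, self.linker.mw_Da, self.linker.leaving_group_Da
            )
            if abs(self.per_drug_mass_override_Da - derived) > 5.0:
                raise ConfigurationError(
                    f"per_drug_mass_override_Da={self.per_drug_mass_override_Da} "
                    f"is more than 5 Da from the component-derived {derived:.2f}"
                )


def mass_addition(
    drug_mw_Da: float,
    linker_mw_Da: float,
    leaving_group_Da: float = NHS_LEAVING_GROUP_DA,
) -> float:
    """Mass added per conjugated drug-linker: drug + linker - leaving group."""
    return drug_mw_Da + linker_mw_Da - leaving_group_Da


def per_drug_mass_addition(design: ConjugateDesign) -> float:
    """Per-drug mass addition for a design, honouring any explicit override."""
    if design.drug is None:  # type: ignore[unreachable]
        raise ConfigurationError("design.drug is not set")
    if design.linker is None:  # type: ignore[unreachable]
        raise ConfigurationError("design.linker is not set")
    if design.per_drug_mass_override_Da is not None:
        return design.per_drug_mass_override_Da
    return mass_addition(
        design.drug.mw_Da, design.linker.mw_Da, design.linker.leaving_group_Da
    )


# Shipped linker registry (spacer arm in Angstrom, average mass in Da).
DEFAULT_LINKERS: Mapping[str, LinkerSpec] = {
    "SMCC": LinkerSpec("SMCC", spacer_arm_A=8.3, mw_Da=334.32),
    "SM(PEG)2": LinkerSpec("SM(PEG)2", spacer_arm_A=17.6, mw_Da=425.39),
    "SM(PEG)12": LinkerSpec("SM(PEG)12", spacer_arm_A=53.4, mw_Da=865.92),
}

DEFAULT_DRUG = DrugSpec("DM1", mw_Da=DM1_MW_DA, lambda_max_nm=252.0)

DEFAULT_ANTIBODY = AntibodySpec(
    "trastuzumab", mw_formula_Da=145_423.0, mw_measured_Da=147_836.9
)


def lookup_linker(
    name: str, registry: Optional[Mapping[str, LinkerSpec]] = None
) -> LinkerSpec:
    """Look a linker up by name; raises listing known names on a miss."""
    reg = DEFAULT_LINKERS if registry is None else registry
    try:
        return reg[name]
    except KeyError:
        raise UnknownLinkerError(
            f"unknown linker {name!r}; known linkers: {sorted(reg)}"
        ) from None
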