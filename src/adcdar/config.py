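"""Physical-constant configuration: shipped defaults, overridable per run."""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Union

from .chem import AntibodySpec, ConjugateDesign, DrugSpec, LinkerSpec, lookup_linker
from .errors import ConfigurationError
from .extinction import ExtinctionSet


@dataclass(frozen=True)
class Constants:
    antibody: AntibodySpec
    drug: DrugSpec
    linkers: Mapping[str, LinkerSpec]
    extinctions: ExtinctionSet
    path_cm: float

    def design(
        self,
        linker_name: str,
        per_drug_mass_override_Da: Optional[float] = None,
    ) -> ConjugateDesign:
        return ConjugateDesign(
            antibody=self.antibody,
            drug=self.drug,
            linker=lookup_linker(linker_name, self.linkers),
            per_drug_mass_override_Da=per_drug_mass_override_Da,
        )


def _parse(raw: dict) -> Constants:
    try:
        antibody = AntibodySpec(**raw["antibody"])
        drug = DrugSpec(**raw["drug"])
        linkers = {d["name"]: LinkerSpec(**d) for d in raw["linkers"]}
        extinctions = ExtinctionSet.from_dict(raw["extinctions"])
        path_cm = float(raw.get("path_cm", 0.56))
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"invalid constants config: {exc}") from exc
    return Constants(antibody, drug, linkers, extinctions, path_cm)


def load_constants(path: Optional[Union[str, Path]] = None) -> Constants:
    """Load constants from a JSON file, or the package's shipped defaults."""
    if path is None:
        text = (
            resources.files("adcdar").joinpath("data/constants.json").read_text()
        )
    else:
        text = Path(path).read_text()
    return _parse(json.loads(text))
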