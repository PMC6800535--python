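"""Assembly of per-conjugate MS and UV DAR results into one comparison table.

Two serializations exist: a display CSV with one-decimal rounding and
thousands separators, and a machine CSV carrying full precision for exact
round trips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .ms_dar import MSDarResult
from .uv_dar import UVDarResult

_COLUMNS = [
    "sample",
    "measured_mass_Da",
    "mass_shift_Da",
    "per_drug_mass_Da",
    "dar_ms",
    "dar_uv",
]


@dataclass
class DarTable:
    """Rows of (sample, masses, per-method DARs); reference row first."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.data.columns) != _COLUMNS:
            raise ConfigurationError(f"DarTable needs columns {_COLUMNS}")


def build_dar_table(
    results: Sequence[Union[MSDarResult, UVDarResult]],
    reference: Optional[tuple[str, float]] = None,
) -> DarTable:
    """Merge MS and UV results by sample id.

    ``reference`` is an optional (name, measured mass) pair rendered as the
    leading row with empty shift/DAR cells.  A duplicate sample/method pair
    is an error; a sample missing one method leaves that cell empty (NaN).
    """
    rows: dict[str, dict] = {}
    order: list[str] = []
    for res in results:
        sample = res.sample_id or "sample"
        if sample not in rows:
            rows[sample] = {c: np.nan for c in _COLUMNS}
            rows[sample]["sample"] = sample
            order.append(sample)
        row = rows[sample]
        if isinstance(res, MSDarResult):
            if not np.isnan(row["dar_ms"]):
                raise ConfigurationError(f"duplicate MS result for {sample!r}")
            row["measured_mass_Da"] = res.conjugate_mass_Da
            row["mass_shift_Da"] = res.mass_shift_Da
            row["per_drug_mass_Da"] = res.per_drug_mass_Da
            row["dar_ms"] = res.dar
        elif isinstance(res, UVDarResult):
            if not np.isnan(row["dar_uv"]):
                raise ConfigurationError(f"duplicate UV result for {sample!r}")
            row["dar_uv"] = res.dar
        else:
            raise ConfigurationError(f"unsupported result type {type(res)!r}")
    records = []
    if reference is not None:
        name, mass = reference
        records.append(
            {
                "sample": name,
                "measured_mass_Da": mass,
                "mass_shift_Da": np.nan,
                "per_drug_mass_Da": np.nan,
                "dar_ms": np.nan,
                "dar_uv": np.nan,
            }
        )
    records.extend(rows[s] for s in order)
    return DarTable(pd.DataFrame(records, columns=_COLUMNS))


@dataclass(frozen=True)
class AgreementSummary:
    differences: pd.DataFrame  # sample, dar_ms, dar_uv, difference
    mean_abs_difference: float


def method_agreement(table: DarTable) -> AgreementSummary:
    """Signed dar_ms - dar_uv per complete row, plus the mean absolute gap."""
    complete = table.data.dropna(subset=["dar_ms", "dar_uv"]).copy()
    if complete.empty:
        warnings.warn("no rows carry both MS and UV DARs", stacklevel=2)
        empty = pd.DataFrame(columns=["sample", "dar_ms", "dar_uv", "difference"])
        return AgreementSummary(empty, float("nan"))
    complete["difference"] = complete["dar_ms"] - complete["dar_uv"]
    diffs = complete[["sample", "dar_ms", "dar_uv", "difference"]].reset_index(
        drop=True
    )
    return AgreementSummary(diffs, float(complete["difference"].abs().mean()))


def _fmt_mass(x: float) -> str:
    return "" if pd.isna(x) else f"{x:,.1f}"


def _fmt_dar(x: float) -> str:
    return "" if pd.isna(x) else f"{x:.1f}"


def write_display_csv(table: DarTable, path: Union[str, Path]) -> None:
    """Human-readable CSV: one decimal, thousands separators in masses."""
    out = table.data.copy()
    for col in ("measured_mass_Da", "mass_shift_Da", "per_drug_mass_Da"):
        out[col] = out[col].map(_fmt_mass)
    for col in ("dar_ms", "dar_uv"):
        out[col] = out[col].map(_fmt_dar)
    out.to_csv(path, index=False, quoting=1)


def write_machine_csv(table: DarTable, path: Union[str, Path]) -> None:
    """Full-precision CSV that round-trips through read_machine_csv."""
    table.data.to_csv(path, index=False, float_format="%.17g")


def read_machine_csv(path: Union[str, Path]) -> DarTable:
    df = pd.read_csv(path)
    df["sample"] = df["sample"].astype(str)
    return DarTable(df[_COLUMNS])
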