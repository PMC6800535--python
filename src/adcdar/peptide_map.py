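"""In-silico tryptic digestion with conjugation-blocked lysines.

Lysine-directed conjugation leaves the modified lysines uncleavable by
trypsin, so the digest of a conjugate merges peptides across each blocked
site.  Comparing the unmodified and modified peptide sets reproduces, at the
set level, how a peptide map evidences conjugation.

Residue positions are 0-based indices into the sequence string.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import FrozenSet, Iterable, Union

import pandas as pd
from Bio import SeqIO

from .errors import ConfigurationError, MapComparisonError

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinSequence:
    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - STANDARD_AA
        if bad:
            raise ConfigurationError(
                f"sequence {self.id!r} has non-standard residues {sorted(bad)}"
            )
        if not self.residues:
            raise ConfigurationError(f"sequence {self.id!r} is empty")


@dataclass(frozen=True)
class Peptide:
    """One digest product: [start, end) slice of the parent sequence."""

    start: int
    end: int
    sequence: str
    blocked_sites_contained: FrozenSet[int] = frozenset()


@dataclass(frozen=True)
class DigestResult:
    parent_id: str
    parent_length: int
    peptides: tuple[Peptide, ...]

    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]


def cleavage_sites(residues: str, blocked_positions: FrozenSet[int]) -> list[int]:
    """0-based positions i such that trypsin cuts after residue i.

    Cuts C-terminal to K and R unless the next residue is proline or the
    position is a blocked (conjugated) lysine.  The terminal residue is never
    a cut site.
    """
    sites = []
    for i, aa in enumerate(residues[:-1]):
        if aa not in "KR":
            continue
        if residues[i + 1] == "P":
            continue
        if aa == "K" and i in blocked_positions:
            continue
        sites.append(i)
    return sites


def tryptic_digest(
    seq: ProteinSequence,
    blocked_positions: Iterable[int] = (),
) -> DigestResult:
    """Digest with zero missed cleavages, skipping blocked lysines."""
    blocked = frozenset(int(i) for i in blocked_positions)
    for i in blocked:
        if i < 0 or i >= len(seq.residues) or seq.residues[i] != "K":
            raise ConfigurationError(
                f"blocked position {i} does not index a K residue in {seq.id!r}"
            )
    sites = cleavage_sites(seq.residues, blocked)
    bounds = [0] + [i + 1 for i in sites] + [len(seq.residues)]
    peptides = []
    for start, end in zip(bounds[:-1], bounds[1:]):
        contained = frozenset(i for i in blocked if start <= i < end)
        peptides.append(
            Peptide(start, end, seq.residues[start:end], contained)
        )
    return DigestResult(seq.id, len(seq.residues), tuple(peptides))


@dataclass(frozen=True)
class MapDifference:
    """Peptides present in exactly one of two digests of the same parent."""

    only_in_unmodified: tuple[Peptide, ...]
    only_in_modified: tuple[Peptide, ...]

    @property
    def is_empty(self) -> bool:
        return not self.only_in_unmodified and not self.only_in_modified

    def merge_explanations(self) -> dict[Peptide, FrozenSet[int]]:
        """For each gained (merged) peptide, the blocked sites inside it."""
        return {
            p: p.blocked_sites_contained
            for p in self.only_in_modified
            if p.blocked_sites_contained
        }


def compare_maps(unmodified: DigestResult, modified: DigestResult) -> MapDifference:
    """Set difference of two digests of the same parent sequence."""
    if unmodified.parent_length != modified.parent_length:
        raise MapComparisonError(
            "digests come from parents of different lengths "
            f"({unmodified.parent_length} vs {modified.parent_length})"
        )
    key = lambda p: (p.start, p.end, p.sequence)
    unmod = {key(p): p for p in unmodified.peptides}
    mod = {key(p): p for p in modified.peptides}
    return MapDifference(
        only_in_unmodified=tuple(
            unmod[k] for k in sorted(unmod.keys() - mod.keys())
        ),
        only_in_modified=tuple(
            mod[k] for k in sorted(mod.keys() - unmod.keys())
        ),
    )


def read_fasta(path: Union[str, Path]) -> list[ProteinSequence]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ConfigurationError(f"no FASTA records in {path}")
    return [ProteinSequence(r.id, str(r.seq).upper()) for r in records]


def write_peptide_csv(digest: DigestResult, path: Union[str, Path]) -> None:
    pd.DataFrame(
        [
            {
                "start": p.start,
                "end": p.end,
                "sequence": p.sequence,
                "blocked_sites": ";".join(map(str, sorted(p.blocked_sites_contained))),
            }
            for p in digest.peptides
        ]
    ).to_csv(path, index=False)
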