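"""Protein sequences, analysis regions, and functional-domain annotations.

Coordinates are 1-based and inclusive on both ends throughout the package,
matching the residue numbering conventions of protein reference sequences
(e.g. L203 is the 203rd residue). A :class:`DomainMap` holds an ordered,
non-overlapping set of domain annotations within one :class:`AnalysisRegion`;
residues not covered by any domain remain part of the uniform sampling space
but carry no hypothesis test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from Bio import SeqIO

from .errors import CoordinateError, DomainOverlapError, ParseError

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
#: alphabet accepted in reference sequences ('X' = unknown residue)
SEQUENCE_ALPHABET = AMINO_ACIDS | {"X"}


@dataclass(frozen=True)
class ProteinSequence:
    """A protein reference sequence with a text accession."""

    accession: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues.upper()) - SEQUENCE_ALPHABET
        if bad:
            raise ParseError(
                f"sequence {self.accession!r} contains non-amino-acid "
                f"letters: {sorted(bad)}"
            )
        object.__setattr__(self, "residues", self.residues.upper())

    @property
    def length(self) -> int:
        return len(self.residues)

    def residue_at(self, position: int) -> str:
        """One-letter residue at a 1-based position."""
        if not 1 <= position <= self.length:
            raise CoordinateError(
                f"position {position} outside sequence {self.accession!r} "
                f"(1..{self.length})"
            )
        return self.residues[position - 1]

    @classmethod
    def from_fasta(cls, path: Union[str, Path]) -> "ProteinSequence":
        """Read the first record of a FASTA file."""
        record = next(SeqIO.parse(str(path), "fasta"), None)
        if record is None:
            raise ParseError(f"no FASTA record found in {path}")
        return cls(accession=record.id, residues=str(record.seq))

    def to_fasta(self, path: Union[str, Path]) -> None:
        with open(path, "w") as handle:
            handle.write(f">{self.accession}\n")
            for i in range(0, self.length, 60):
                handle.write(self.residues[i : i + 60] + "\n")


@dataclass(frozen=True)
class AnalysisRegion:
    """The residue interval over which the null distributes mutations.

    Either the full protein or a sub-range such as an intracellular
    C-terminal tail.
    """

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (isinstance(self.start, int) and isinstance(self.end, int)):
            raise CoordinateError("region bounds must be integers")
        if not 1 <= self.start <= self.end:
            raise CoordinateError(
                f"invalid region {self.start}..{self.end}: need 1 <= start <= end"
            )

    @property
    def length(self) -> int:
        """L_X, the number of residues in the region."""
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    @classmethod
    def full(cls, sequence: ProteinSequence) -> "AnalysisRegion":
        return cls(1, sequence.length)


@dataclass(frozen=True)
class DomainAnnotation:
    """One named functional domain, 1-based inclusive residue interval."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise CoordinateError(
                f"domain {self.name!r}: start {self.start} > end {self.end}"
            )

    @property
    def length(self) -> int:
        """L_j."""
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class DomainMap:
    """Ordered, pairwise non-overlapping domains inside one region.

    Overlapping annotations are rejected loudly rather than double-counted,
    because per-domain mutation tallies are interpreted as a partition-style
    count.
    """

    region: AnalysisRegion
    domains: tuple[DomainAnnotation, ...]

    def __init__(
        self, region: AnalysisRegion, domains: Sequence[DomainAnnotation]
    ) -> None:
        object.__setattr__(self, "region", region)
        object.__setattr__(self, "domains", tuple(domains))
        self._validate()

    def _validate(self) -> None:
        if len(self.domains) < 1:
            raise CoordinateError("a domain map requires at least one domain")
        for dom in self.domains:
            if dom.start < self.region.start or dom.end > self.region.end:
                raise CoordinateError(
                    f"domain {dom.name!r} ({dom.start}..{dom.end}) lies outside "
                    f"region {self.region.start}..{self.region.end}"
                )
        by_start = sorted(self.domains, key=lambda d: d.start)
        for left, right in zip(by_start, by_start[1:]):
            if right.start <= left.end:
                raise DomainOverlapError(
                    f"domains {left.name!r} ({left.start}..{left.end}) and "
                    f"{right.name!r} ({right.start}..{right.end}) overlap"
                )

    @property
    def J(self) -> int:
        return len(self.domains)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.domains]

    @property
    def lengths(self) -> np.ndarray:
        """Vector of L_j in file order."""
        return np.array([d.length for d in self.domains], dtype=np.int64)

    def domain_of(self, position: int) -> Optional[DomainAnnotation]:
        """The unique domain containing ``position``, or None between domains."""
        if not self.region.contains(position):
            raise CoordinateError(
                f"position {position} outside region "
                f"{self.region.start}..{self.region.end}"
            )
        for dom in self.domains:
            if dom.contains(position):
                return dom
        return None

    def residue_domain_index(self) -> np.ndarray:
        """Per-residue domain index over the region.

        Entry ``i`` covers residue ``region.start + i`` and holds the 0-based
        index of its domain in file order, or -1 for inter-domain residues.
        """
        idx = np.full(self.region.length, -1, dtype=np.int64)
        for j, dom in enumerate(self.domains):
            idx[dom.start - self.region.start : dom.end - self.region.start + 1] = j
        return idx

    def subset(self, names: Sequence[str]) -> "DomainMap":
        """A new map restricted to the named domains (file order preserved)."""
        wanted = set(names)
        unknown = wanted - set(self.names)
        if unknown:
            raise KeyError(f"unknown domain name(s): {sorted(unknown)}")
        return DomainMap(self.region, [d for d in self.domains if d.name in wanted])


def load_domain_map(path: Union[str, Path], region: AnalysisRegion) -> DomainMap:
    """Read a tab-separated domain table (``name<TAB>start<TAB>end``).

    Header row required; comment lines start with ``#``. File order is
    preserved in the resulting map.
    """
    domains: list[DomainAnnotation] = []
    with open(path) as handle:
        header = None
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                for col in ("name", "start", "end"):
                    if col not in header:
                        raise ParseError(
                            f"{path}: missing column {col!r} in header (line {lineno})"
                        )
                continue
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            row = dict(zip(header, fields))
            try:
                start, end = int(row["start"]), int(row["end"])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            domains.append(DomainAnnotation(row["name"].strip(), start, end))
    if header is None:
        raise ParseError(f"{path}: empty domain table")
    return DomainMap(region, domains)


def write_domain_map(dmap: DomainMap, path: Union[str, Path]) -> None:
    """Write a domain map back to the tab-separated table format."""
    with open(path, "w") as handle:
        handle.write("name\tstart\tend\n")
        for dom in dmap.domains:
            handle.write(f"{dom.name}\t{dom.start}\t{dom.end}\n")
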