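"""Variant catalog parsing, classification, and the hotspot-test input set.

A catalog row carries a variant label, a variant class, a clinical-severity
label, and an optional allele frequency. Only single-amino-acid variants
(missense substitutions and single-residue deletions) enter the hotspot test:
truncating classes (nonsense, frameshift), splice-site and gene-level events,
and non-initiation variants are excluded because the uniform-per-residue null
is meaningless for them.

Label grammars accepted by :func:`parse_variant`:

* one-letter shorthand: ``L203P``, ``R213*``, ``K552del``
* three-letter HGVS-p: ``p.Leu203Pro``, ``p.(Leu203Pro)``, ``p.Arg213Ter``,
  ``p.Lys552del`` (the ``p.`` prefix and parentheses are optional)
"""

from __future__ import annotations

import enum
import re
import warnings
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .domains import AnalysisRegion, ProteinSequence
from .errors import EmptySetError, ParseError, ReferenceMismatchError


class VariantClass(str, enum.Enum):
    MISSENSE = "missense"
    SINGLE_AA_DELETION = "single_aa_deletion"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE_SITE = "splice_site"
    GENE_DELETION = "gene_deletion"
    NON_INITIATION = "non_initiation"
    SILENT = "silent"


class Severity(str, enum.Enum):
    MILD_BFNE = "mild_bfne"
    UNCERTAIN = "uncertain"
    SEVERE_EE = "severe_ee"
    NONPATHOGENIC = "nonpathogenic"
    SILENT_CONTROL = "silent_control"


#: classes whose records carry a residue position
POSITIONAL_CLASSES = frozenset(
    {
        VariantClass.MISSENSE,
        VariantClass.SINGLE_AA_DELETION,
        VariantClass.NONSENSE,
        VariantClass.SILENT,
    }
)

#: severity labels counted as pathogenic for the "all-pathogenic" filter
PATHOGENIC_SEVERITIES = frozenset(
    {Severity.MILD_BFNE, Severity.UNCERTAIN, Severity.SEVERE_EE}
)

AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

_ONE_LETTER = re.compile(r"^([ACDEFGHIKLMNPQRSTVWY])(\d+)(?:([ACDEFGHIKLMNPQRSTVWY*])|del)$")
_THREE_LETTER = re.compile(r"^(?:p\.)?\(?([A-Z][a-z]{2})(\d+)(?:([A-Z][a-z]{2})|del)\)?$")


@dataclass(frozen=True)
class VariantRecord:
    """One parsed variant."""

    raw_label: str
    variant_class: VariantClass
    severity: Severity
    position: Optional[int] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None  # one-letter code, "del", or None
    allele_frequency_pct: Optional[float] = None
    source: Optional[str] = None

    def __post_init__(self) -> None:
        positional = self.variant_class in POSITIONAL_CLASSES
        if positional and (self.position is None or self.ref_aa is None):
            raise ParseError(
                f"{self.raw_label!r}: class {self.variant_class.value} requires "
                "a residue position and reference residue"
            )
        if not positional and self.position is not None:
            raise ParseError(
                f"{self.raw_label!r}: class {self.variant_class.value} must not "
                "carry a residue position"
            )

    @property
    def substitution_key(self) -> tuple:
        """Identity for duplicate collapsing: (position, ref, alt) when
        positional, otherwise the raw label."""
        if self.variant_class in POSITIONAL_CLASSES:
            return (self.position, self.ref_aa, self.alt_aa)
        return (self.raw_label,)


def parse_variant(
    token: str, sequence: Optional[ProteinSequence] = None
) -> VariantRecord:
    """Parse a protein variant label into a positional :class:`VariantRecord`.

    The class is inferred from the grammar: ``del`` suffix yields a
    single-residue deletion, a ``*``/``Ter`` alternate yields nonsense,
    ref == alt yields silent, anything else missense. Severity defaults to
    ``uncertain`` and is normally overwritten by the catalog loader.

    When ``sequence`` is given the stated reference residue is checked
    against it.
    """
    token = token.strip()
    if not token:
        raise ParseError("empty variant token")
    m = _ONE_LETTER.match(token)
    if m:
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        alt = alt if alt is not None else "del"
    else:
        m = _THREE_LETTER.match(token)
        if not m:
            raise ParseError(f"unrecognized variant syntax: {token!r}")
        ref3, pos, alt3 = m.group(1), int(m.group(2)), m.group(3)
        if ref3 not in AA3_TO_1 or ref3 == "Ter":
            raise ParseError(f"unknown reference residue in {token!r}")
        ref = AA3_TO_1[ref3]
        if alt3 is None:
            alt = "del"
        elif alt3 in AA3_TO_1:
            alt = AA3_TO_1[alt3]
        else:
            raise ParseError(f"unknown alternate residue in {token!r}")
    if alt == "del":
        vclass = VariantClass.SINGLE_AA_DELETION
    elif alt == "*":
        vclass = VariantClass.NONSENSE
    elif alt == ref:
        vclass = VariantClass.SILENT
    else:
        vclass = VariantClass.MISSENSE
    if sequence is not None:
        expected = sequence.residue_at(pos)
        if expected != ref:
            raise ReferenceMismatchError(
                f"{token!r}: reference sequence has {expected} at position "
                f"{pos}, not {ref}"
            )
    return VariantRecord(
        raw_label=token,
        variant_class=vclass,
        severity=Severity.UNCERTAIN,
        position=pos,
        ref_aa=ref,
        alt_aa=alt,
    )


def format_variant(record: VariantRecord) -> str:
    """Canonical one-letter token for a positional record."""
    if record.variant_class not in POSITIONAL_CLASSES:
        return record.raw_label
    suffix = "del" if record.alt_aa == "del" else record.alt_aa
    return f"{record.ref_aa}{record.position}{suffix}"


@dataclass
class VariantCatalog:
    """A compiled variant table; identical substitutions are collapsed."""

    records: list[VariantRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: dict[tuple, VariantRecord] = {}
        for rec in self.records:
            seen.setdefault((rec.variant_class, *rec.substitution_key), rec)
        self.records = list(seen.values())

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @classmethod
    def from_tsv(
        cls,
        path: Union[str, Path],
        sequence: Optional[ProteinSequence] = None,
    ) -> "VariantCatalog":
        """Read the standard catalog table.

        Tab-separated with header ``variant  class  severity  allele_freq_pct
        source``; comment lines start with ``#``. Positional classes have
        their ``variant`` token parsed and checked for consistency with the
        stated class (and with ``sequence`` when given).
        """
        records: list[VariantRecord] = []
        with open(path) as handle:
            header = None
            for lineno, raw in enumerate(handle, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                fields = line.split("\t")
                if header is None:
                    header = [f.strip().lower() for f in fields]
                    for col in ("variant", "class", "severity"):
                        if col not in header:
                            raise ParseError(
                                f"{path}: missing column {col!r} (line {lineno})"
                            )
                    continue
                row = dict(zip(header, fields))
                try:
                    vclass = VariantClass(row["class"].strip())
                    severity = Severity(row["severity"].strip())
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: {exc}") from exc
                freq_raw = (row.get("allele_freq_pct") or "").strip()
                freq = float(freq_raw) if freq_raw else None
                source = (row.get("source") or "").strip() or None
                token = row["variant"].strip()
                if vclass in POSITIONAL_CLASSES:
                    try:
                        parsed = parse_variant(token, sequence)
                    except ParseError as exc:
                        raise ParseError(f"{path}: line {lineno}: {exc}") from exc
                    if parsed.variant_class is not vclass:
                        raise ParseError(
                            f"{path}: line {lineno}: token {token!r} parses as "
                            f"{parsed.variant_class.value}, file says {vclass.value}"
                        )
                    rec = replace(
                        parsed,
                        severity=severity,
                        allele_frequency_pct=freq,
                        source=source,
                    )
                else:
                    rec = VariantRecord(
                        raw_label=token,
                        variant_class=vclass,
                        severity=severity,
                        allele_frequency_pct=freq,
                        source=source,
                    )
                records.append(rec)
        if header is None:
            raise ParseError(f"{path}: empty catalog file")
        return cls(records=records, provenance=str(path))

    def to_tsv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as handle:
            handle.write("variant\tclass\tseverity\tallele_freq_pct\tsource\n")
            for rec in self.records:
                freq = (
                    "" if rec.allele_frequency_pct is None
                    else f"{rec.allele_frequency_pct:g}"
                )
                handle.write(
                    f"{format_variant(rec)}\t{rec.variant_class.value}\t"
                    f"{rec.severity.value}\t{freq}\t{rec.source or ''}\n"
                )


@dataclass(frozen=True)
class MutationSet:
    """The multiset S of single-amino-acid variant positions.

    Distinct substitutions at one codon contribute separately, so a position
    may repeat; ``size`` (|S|) is the number of contributing unique variants.
    """

    positions: np.ndarray
    region: AnalysisRegion

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "positions", np.sort(pos))
        outside = (pos < self.region.start) | (pos > self.region.end)
        if outside.any():
            bad = pos[outside][0]
            raise EmptySetError(
                f"mutation position {bad} outside region "
                f"{self.region.start}..{self.region.end}"
            )

    @property
    def size(self) -> int:
        """|S|."""
        return int(self.positions.size)


@dataclass(frozen=True)
class ClassificationSummary:
    """Exhaustive, mutually exclusive tallies of a catalog."""

    by_class: pd.Series
    by_severity: pd.Series
    total: int


def classify_counts(catalog: VariantCatalog) -> ClassificationSummary:
    """Tally records by variant class and by severity label.

    Both tallies are exhaustive over the enumerations (absent levels appear
    with count zero) and each sums to the record count.
    """
    class_counts = Counter(rec.variant_class for rec in catalog)
    sev_counts = Counter(rec.severity for rec in catalog)
    by_class = pd.Series(
        {vc.value: class_counts.get(vc, 0) for vc in VariantClass}, dtype=int
    )
    by_severity = pd.Series(
        {sv.value: sev_counts.get(sv, 0) for sv in Severity}, dtype=int
    )
    return ClassificationSummary(by_class, by_severity, total=len(catalog))


def _normalize_severity_filter(
    severity_filter: Union[str, Iterable[Union[str, Severity]]],
) -> frozenset[Severity]:
    if isinstance(severity_filter, str):
        if severity_filter == "all-pathogenic":
            return PATHOGENIC_SEVERITIES
        return frozenset({Severity(severity_filter)})
    return frozenset(Severity(s) for s in severity_filter)


def select_mhf_input(
    catalog: VariantCatalog,
    region: AnalysisRegion,
    severity_filter: Union[str, Iterable[Union[str, Severity]]] = "all-pathogenic",
) -> MutationSet:
    """Filter a catalog into the hotspot-test input set S.

    Keeps single-amino-acid classes only (missense, single-residue deletions,
    and — for the control pathway — silent substitutions; truncating and
    gene-level classes are incompatible with the per-residue null); drops
    missense at the primary start codon and non-initiation records; keeps
    positions inside ``region``; applies the severity filter
    (``"all-pathogenic"`` = mild ∪ uncertain ∪ severe, which excludes the
    silent/nonpathogenic control labels).
    """
    severities = _normalize_severity_filter(severity_filter)
    keep_classes = {
        VariantClass.MISSENSE,
        VariantClass.SINGLE_AA_DELETION,
        VariantClass.SILENT,
    }
    positions = [
        rec.position
        for rec in catalog
        if rec.variant_class in keep_classes
        and rec.position != 1  # primary start codon
        and rec.severity in severities
        and region.contains(rec.position)
    ]
    if not positions:
        warnings.warn(
            "severity/region filter left an empty mutation set; "
            "the hotspot test will refuse to run on |S| = 0",
            stacklevel=2,
        )
    return MutationSet(np.array(positions, dtype=np.int64), region)
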