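"""Exact 2x2 association test between hotspot membership and severity.

The contingency table crosses hotspot-domain membership (rows) against the
severe clinical class versus the remaining pathogenic classes (columns).
The test is Fisher's exact test computed from the hypergeometric
distribution with exact integer arithmetic, using the minimum-likelihood
two-sided convention (sum the probabilities of all tables, at the observed
margins, whose point probability does not exceed the observed table's).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Iterable, Union

from .catalog import (
    PATHOGENIC_SEVERITIES,
    Severity,
    VariantCatalog,
    VariantClass,
)
from .domains import DomainMap
from .errors import EmptySetError


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows = in-hotspot / elsewhere,
    columns = severe / other-pathogenic."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.total < 1:
            raise EmptySetError("all-zero contingency table: test undefined")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_rows(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


def _point_probability(a: int, row1: int, row2: int, col1: int) -> Fraction:
    """Hypergeometric probability of cell a at fixed margins, exact."""
    total = row1 + row2
    return Fraction(
        comb(row1, a) * comb(row2, col1 - a), comb(total, col1)
    )


def fisher_exact_2x2(
    table: ContingencyTable2x2, sidedness: str = "two-sided"
) -> float:
    """Fisher's exact test p-value for a 2x2 table.

    ``sidedness`` is ``"two-sided"`` (minimum-likelihood convention) or
    ``"one-sided-greater"`` (right tail on the [0,0] cell). All table
    probabilities at fixed margins share the denominator C(N, col1), so the
    test compares and sums integer numerators: tie handling and the final
    p-value are exact, with the float conversion happening only at the end.
    """
    row1, row2 = table.a + table.b, table.c + table.d
    col1 = table.a + table.c
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    numerator = [comb(row1, x) * comb(row2, col1 - x) for x in range(lo, hi + 1)]
    num_obs = numerator[table.a - lo]
    if sidedness == "one-sided-greater":
        num_sum = sum(numerator[table.a - lo :])
    elif sidedness == "two-sided":
        num_sum = sum(n for n in numerator if n <= num_obs)
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    p = Fraction(num_sum, comb(row1 + row2, col1))
    return float(min(Fraction(1), p))


def build_contingency(
    catalog: VariantCatalog,
    dmap: DomainMap,
    hotspot_domains: Iterable[str],
    severe_group: Union[Severity, Iterable[Severity]] = Severity.SEVERE_EE,
) -> ContingencyTable2x2:
    """Cross-tabulate single-amino-acid pathogenic variants.

    Rows: position inside one of ``hotspot_domains`` vs elsewhere in the
    region. Columns: severity in ``severe_group`` vs the other pathogenic
    severities. The stratification (unit = variant; hotspot set; severity
    split) is explicit because different choices are defensible.
    """
    hotspot_domains = list(hotspot_domains)
    unknown = set(hotspot_domains) - set(dmap.names)
    if unknown:
        raise KeyError(f"unknown hotspot domain name(s): {sorted(unknown)}")
    if isinstance(severe_group, Severity):
        severe_group = {severe_group}
    severe_group = set(severe_group)
    hotspots = dmap.subset(hotspot_domains) if hotspot_domains else None
    a = b = c = d = 0
    keep = {VariantClass.MISSENSE, VariantClass.SINGLE_AA_DELETION}
    for rec in catalog:
        if rec.variant_class not in keep or rec.severity not in PATHOGENIC_SEVERITIES:
            continue
        if rec.position == 1 or not dmap.region.contains(rec.position):
            continue
        in_hotspot = (
            hotspots is not None and hotspots.domain_of(rec.position) is not None
        )
        severe = rec.severity in severe_group
        if in_hotspot and severe:
            a += 1
        elif in_hotspot:
            b += 1
        elif severe:
            c += 1
        else:
            d += 1
    return ContingencyTable2x2(a, b, c, d)
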