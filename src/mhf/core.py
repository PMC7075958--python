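"""The bootstrap hotspot test.

Null model: single-amino-acid mutations are equally likely at every residue
of the analysis region, with no further association between mutations and
domains. A bootstrap draws K sets of |S| positions uniformly with replacement
from the region, tallies them per domain, and compares against the observed
per-domain counts with a right-tailed add-one empirical p-value

    P_hat_j = (1 + #{k : Dtilde_j(k) >= D_j}) / (K + 1)

whose range [1/(K+1), 1] makes it super-uniform under the null. Raw p-values
are Bonferroni-adjusted over the J domains of the analysis. An exact binomial
tail is provided as an analytic oracle for the same null.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import MutationSet, VariantCatalog, select_mhf_input
from .domains import AnalysisRegion, DomainMap
from .errors import CoordinateError, EmptySetError

#: reporting thresholds for significance stars, most stringent first
STAR_THRESHOLDS = ((0.005, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float) -> str:
    """Textual significance stars: *** p<0.005, ** p<0.01, * p<0.05."""
    for threshold, mark in STAR_THRESHOLDS:
        if p < threshold:
            return mark
    return ""


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap iteration count, master seed, and flagging level."""

    K: int = 10_000
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class NullCountMatrix:
    """K x J matrix of bootstrapped per-domain counts Dtilde_j(k)."""

    counts: np.ndarray
    n: int
    region: AnalysisRegion

    @property
    def K(self) -> int:
        return int(self.counts.shape[0])

    @property
    def J(self) -> int:
        return int(self.counts.shape[1])


@dataclass(frozen=True)
class HotspotResult:
    """Per-domain hotspot table with run provenance.

    ``table`` columns: domain, start, end, L, D, E_hat, E_analytic, p_raw,
    p_bonferroni, significant, stars.
    """

    table: pd.DataFrame
    n: int
    K: int
    seed: int
    alpha: float
    region: AnalysisRegion
    severity_filter: str = ""

    @property
    def significant_domains(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "domain"])


def observed_counts(mutations: MutationSet, dmap: DomainMap) -> np.ndarray:
    """Per-domain tally D_j of observed mutation positions (with multiplicity)."""
    pos = mutations.positions
    if pos.size and (
        pos.min() < dmap.region.start or pos.max() > dmap.region.end
    ):
        raise CoordinateError("mutation position outside the domain map's region")
    idx = dmap.residue_domain_index()
    counts = np.zeros(dmap.J, dtype=np.int64)
    if pos.size:
        dom = idx[pos - dmap.region.start]
        inside = dom >= 0
        np.add.at(counts, dom[inside], 1)
    return counts


def bootstrap_null(
    region: AnalysisRegion,
    dmap: DomainMap,
    n: int,
    config: BootstrapConfig,
    rng: Optional[np.random.Generator] = None,
    replace: bool = True,
) -> NullCountMatrix:
    """Draw K bootstrapped mutation sets of size n and tally them per domain.

    Positions are i.i.d. uniform over the region's residues (with
    replacement by default; ``replace=False`` is offered for sensitivity
    analysis only). Results are bit-stable for a given (seed, K, n, region)
    regardless of internal chunking.
    """
    if n < 1:
        raise EmptySetError("cannot bootstrap an empty mutation set (n = 0)")
    if dmap.region != region:
        raise CoordinateError("domain map was built for a different region")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = region.length
    if not replace and n > L:
        raise ValueError(f"cannot draw {n} positions without replacement from {L}")
    idx = dmap.residue_domain_index()
    J = dmap.J
    counts = np.empty((config.K, J), dtype=np.int64)
    # chunk rows to bound memory; a single Generator consumed row-major keeps
    # the draws identical to a one-shot (K, n) call
    chunk = max(1, 4_000_000 // max(n, 1))
    for lo in range(0, config.K, chunk):
        hi = min(config.K, lo + chunk)
        if replace:
            draws = rng.integers(0, L, size=(hi - lo, n))
        else:
            draws = np.stack(
                [rng.choice(L, size=n, replace=False) for _ in range(hi - lo)]
            )
        dom = idx[draws] + 1  # 0 = inter-domain residues
        offsets = np.arange(hi - lo, dtype=np.int64)[:, None] * (J + 1)
        binned = np.bincount(
            (dom + offsets).ravel(), minlength=(hi - lo) * (J + 1)
        ).reshape(hi - lo, J + 1)
        counts[lo:hi] = binned[:, 1:]
    return NullCountMatrix(counts=counts, n=n, region=region)


def empirical_pvalue(observed: int, null_column: np.ndarray) -> float:
    """Right-tailed add-one empirical p-value against one null column."""
    null_column = np.asarray(null_column)
    K = null_column.shape[0]
    exceed = int(np.count_nonzero(null_column >= observed))
    return (1 + exceed) / (K + 1)


def adjust_bonferroni(p_raw: Iterable[float], J: int) -> np.ndarray:
    """Bonferroni adjustment over the J domains tested: min(1, J * p)."""
    p = np.asarray(list(p_raw), dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("raw p-values must lie in (0, 1]")
    return np.minimum(1.0, J * p)


def exact_binomial_pvalue(observed: int, n: int, L_j: int, L_X: int) -> float:
    """Analytic right tail P(Binomial(n, L_j/L_X) >= observed) for the
    uniform-per-residue null; the bootstrap's marginal distribution."""
    if not 0 <= observed <= n:
        raise ValueError(f"observed count {observed} outside 0..{n}")
    if not 0 < L_j <= L_X:
        raise ValueError("need 0 < L_j <= L_X")
    if observed == 0:
        return 1.0
    return float(stats.binom.sf(observed - 1, n, L_j / L_X))


def hotspot_test(
    mutations: MutationSet,
    dmap: DomainMap,
    config: BootstrapConfig = BootstrapConfig(),
    rng: Optional[np.random.Generator] = None,
) -> HotspotResult:
    """Run the hotspot test on an already-filtered mutation set."""
    if mutations.size == 0:
        raise EmptySetError("refusing to run the hotspot test on |S| = 0")
    region = dmap.region
    D = observed_counts(mutations, dmap)
    null = bootstrap_null(region, dmap, mutations.size, config, rng=rng)
    p_raw = np.array(
        [empirical_pvalue(int(D[j]), null.counts[:, j]) for j in range(dmap.J)]
    )
    p_adj = adjust_bonferroni(p_raw, dmap.J)
    lengths = dmap.lengths
    table = pd.DataFrame(
        {
            "domain": dmap.names,
            "start": [d.start for d in dmap.domains],
            "end": [d.end for d in dmap.domains],
            "L": lengths,
            "D": D,
            "E_hat": null.counts.mean(axis=0),
            "E_analytic": mutations.size * lengths / region.length,
            "p_raw": p_raw,
            "p_bonferroni": p_adj,
        }
    )
    table["significant"] = table["p_bonferroni"] <= config.alpha
    table["stars"] = table["p_bonferroni"].map(stars)
    return HotspotResult(
        table=table,
        n=mutations.size,
        K=config.K,
        seed=config.seed,
        alpha=config.alpha,
        region=region,
    )


def run_mhf(
    catalog: VariantCatalog,
    dmap: DomainMap,
    region: Optional[AnalysisRegion] = None,
    severity_filter: Union[str, Iterable[str]] = "all-pathogenic",
    config: BootstrapConfig = BootstrapConfig(),
) -> HotspotResult:
    """Full pipeline: filter the catalog, then bootstrap-test every domain.

    ``region`` defaults to the domain map's region. Provenance (|S|, K, seed,
    severity filter) is recorded on the result.
    """
    if region is None:
        region = dmap.region
    elif region != dmap.region:
        raise CoordinateError("region and domain map disagree")
    mutations = select_mhf_input(catalog, region, severity_filter)
    result = hotspot_test(mutations, dmap, config)
    filt = (
        severity_filter
        if isinstance(severity_filter, str)
        else ",".join(sorted(str(s) for s in severity_filter))
    )
    return dataclasses.replace(result, severity_filter=filt)
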