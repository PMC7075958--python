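"""Synthetic mutation catalogs with known structure, and the
type-I-error / power harness built on them.

Three generators cover the statistical claims of the hotspot test:

* a uniform null (every residue of the region equally likely),
* a mixture alternative: with probability ``pi`` a mutation lands uniformly
  inside a designated hotspot domain (hotspot chosen with probability
  proportional to its length, so ``pi`` is interpretable as total excess
  hotspot mass), otherwise uniformly over the whole region,
* severity labels enriched in hotspots: a hotspot mutation is labeled severe
  with probability ``rho``, any other with a baseline probability.

:func:`run_calibration` replays the full hotspot pipeline over replicate
catalogs and reports per-domain rejection rates at the requested levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import (
    MutationSet,
    Severity,
    VariantCatalog,
    VariantRecord,
    VariantClass,
    select_mhf_input,
)
from .core import BootstrapConfig, adjust_bonferroni, bootstrap_null, empirical_pvalue, observed_counts
from .domains import AnalysisRegion, DomainMap, ProteinSequence

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of one synthetic-catalog experiment.

    ``pi`` is the hotspot placement probability (0 = uniform null);
    ``rho`` the probability a hotspot mutation is labeled severe;
    ``baseline_severe`` the severe probability elsewhere.
    """

    region: AnalysisRegion
    dmap: DomainMap
    n: int = 130
    hotspot_domains: tuple[str, ...] = ()
    pi: float = 0.0
    rho: float = 0.7
    baseline_severe: float = 0.3
    replicates: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.pi <= 1:
            raise ValueError("pi must lie in [0, 1]")
        if not 0 <= self.rho <= 1 or not 0 <= self.baseline_severe <= 1:
            raise ValueError("severity probabilities must lie in [0, 1]")
        if self.n < 1 or self.replicates < 1:
            raise ValueError("n and replicates must be >= 1")
        if self.pi > 0 and not self.hotspot_domains:
            raise ValueError("pi > 0 requires a non-empty hotspot set")
        unknown = set(self.hotspot_domains) - set(self.dmap.names)
        if unknown:
            raise ValueError(f"unknown hotspot domain(s): {sorted(unknown)}")


def simulate_null_set(
    region: AnalysisRegion,
    n: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> MutationSet:
    """n positions i.i.d. uniform over the region's residues."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    positions = rng.integers(region.start, region.end + 1, size=n)
    return MutationSet(positions, region)


def _simulate_positions(design: SimulationDesign, rng: np.random.Generator) -> np.ndarray:
    """Mixture placement: hotspot (length-proportional) w.p. pi, else uniform."""
    region = design.region
    if design.pi == 0.0:
        return rng.integers(region.start, region.end + 1, size=design.n)
    hotspots = [d for d in design.dmap.domains if d.name in set(design.hotspot_domains)]
    lengths = np.array([d.length for d in hotspots], dtype=float)
    weights = lengths / lengths.sum()
    in_hotspot = rng.random(design.n) < design.pi
    positions = rng.integers(region.start, region.end + 1, size=design.n)
    n_hot = int(in_hotspot.sum())
    if n_hot:
        which = rng.choice(len(hotspots), size=n_hot, p=weights)
        offsets = rng.random(n_hot)
        hot_pos = np.array(
            [
                hotspots[w].start + int(o * hotspots[w].length)
                for w, o in zip(which, offsets)
            ]
        )
        positions[in_hotspot] = hot_pos
    return positions


def simulate_clustered_catalog(
    design: SimulationDesign,
    sequence: Optional[ProteinSequence] = None,
    rng: Optional[np.random.Generator] = None,
) -> VariantCatalog:
    """Emit a parseable missense catalog from the mixture design.

    Reference residues come from ``sequence`` when given, otherwise are drawn
    deterministically from the generator; alternates are always != ref.
    Severity is severe with probability ``rho`` inside hotspots and
    ``baseline_severe`` elsewhere; non-severe labels split evenly between
    mild and uncertain.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    positions = _simulate_positions(design, rng)
    hotspot_map = (
        design.dmap.subset(design.hotspot_domains) if design.hotspot_domains else None
    )
    records = []
    for i, pos in enumerate(positions):
        pos = int(pos)
        if sequence is not None:
            ref = sequence.residue_at(pos)
        else:
            ref = str(_AA[rng.integers(0, len(_AA))])
        alt_choices = _AA[_AA != ref]
        alt = str(alt_choices[rng.integers(0, len(alt_choices))])
        in_hotspot = (
            hotspot_map is not None and hotspot_map.domain_of(pos) is not None
        )
        p_severe = design.rho if in_hotspot else design.baseline_severe
        if rng.random() < p_severe:
            severity = Severity.SEVERE_EE
        else:
            severity = (
                Severity.MILD_BFNE if rng.random() < 0.5 else Severity.UNCERTAIN
            )
        records.append(
            VariantRecord(
                raw_label=f"{ref}{pos}{alt}",
                variant_class=VariantClass.MISSENSE,
                severity=severity,
                position=pos,
                ref_aa=ref,
                alt_aa=alt,
                source=f"sim_{i}",
            )
        )
    # distinct records may collide on (position, ref, alt); keep the multiset
    # size honest by re-drawing alternates for collisions
    catalog = VariantCatalog(records=records, provenance="simulated")
    attempts = 0
    while len(catalog) < design.n and attempts < 100:
        seen = {r.substitution_key for r in catalog.records}
        extra = design.n - len(catalog)
        new = []
        for rec in records:
            if rec.substitution_key in seen:
                ref = rec.ref_aa
                alt_choices = [a for a in _AA if a != ref]
                alt = str(alt_choices[int(rng.integers(0, len(alt_choices)))])
                cand = VariantRecord(
                    raw_label=f"{ref}{rec.position}{alt}",
                    variant_class=VariantClass.MISSENSE,
                    severity=rec.severity,
                    position=rec.position,
                    ref_aa=ref,
                    alt_aa=alt,
                    source=rec.source,
                )
                if cand.substitution_key not in seen:
                    seen.add(cand.substitution_key)
                    new.append(cand)
                    extra -= 1
                    if extra == 0:
                        break
        catalog = VariantCatalog(records=catalog.records + new, provenance="simulated")
        attempts += 1
    return catalog


def run_calibration(
    design: SimulationDesign,
    config: BootstrapConfig = BootstrapConfig(K=2_000),
    alphas: Sequence[float] = (0.01, 0.05, 0.1),
) -> pd.DataFrame:
    """Per-domain rejection rates of the full hotspot pipeline.

    For each of ``design.replicates`` synthetic mutation sets a fresh
    bootstrap null is drawn and per-domain raw and Bonferroni-adjusted
    p-values computed; the returned table reports, per domain and level, the
    fraction of replicates with p <= alpha.
    """
    master = np.random.SeedSequence(design.seed)
    child_seeds = master.spawn(design.replicates)
    dmap, region = design.dmap, design.region
    J = dmap.J
    p_raw = np.empty((design.replicates, J))
    p_adj = np.empty((design.replicates, J))
    for r in range(design.replicates):
        rng = np.random.default_rng(child_seeds[r])
        positions = _simulate_positions(design, rng)
        mutations = MutationSet(positions, region)
        D = observed_counts(mutations, dmap)
        null = bootstrap_null(region, dmap, design.n, config, rng=rng)
        p_raw[r] = [
            empirical_pvalue(int(D[j]), null.counts[:, j]) for j in range(J)
        ]
        p_adj[r] = adjust_bonferroni(p_raw[r], J)
    rows = []
    for j, name in enumerate(dmap.names):
        for alpha in alphas:
            rows.append(
                {
                    "domain": name,
                    "alpha": alpha,
                    "raw_rejection_rate": float(np.mean(p_raw[:, j] <= alpha)),
                    "adjusted_rejection_rate": float(np.mean(p_adj[:, j] <= alpha)),
                }
            )
    return pd.DataFrame(rows)
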