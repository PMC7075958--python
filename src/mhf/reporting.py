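"""Result tables, run manifests, and the lollipop plot.

Machine outputs are written as a TSV results table plus a JSON manifest
sufficient to reproduce the run bit-for-bit (inputs digests, seed, K, |S|,
region, package version). Logging never mixes into machine outputs.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import __version__
from .catalog import POSITIONAL_CLASSES, Severity, VariantCatalog
from .core import HotspotResult
from .domains import DomainMap, ProteinSequence

SEVERITY_COLORS = {
    Severity.MILD_BFNE: "#2b6cb0",      # blue
    Severity.UNCERTAIN: "#6b46c1",      # purple
    Severity.SEVERE_EE: "#c53030",      # red
    Severity.NONPATHOGENIC: "#718096",
    Severity.SILENT_CONTROL: "#38a169",
}

RESULT_COLUMNS = [
    "domain", "start", "end", "L", "D", "E_hat", "E_analytic",
    "p_raw", "p_bonferroni", "stars",
]


def file_digest(path: Union[str, Path]) -> str:
    """SHA-256 hex digest of a file's bytes."""
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for block in iter(lambda: handle.read(65536), b""):
            h.update(block)
    return h.hexdigest()


@dataclass(frozen=True)
class RunManifest:
    """Provenance of one hotspot run."""

    command: str
    seed: int
    K: int
    n: int
    region: str
    severity_filter: str = ""
    input_digests: dict = field(default_factory=dict)
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(
            datetime.timezone.utc
        ).isoformat()
    )
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "seed": self.seed,
            "K": self.K,
            "n": self.n,
            "region": self.region,
            "severity_filter": self.severity_filter,
            "input_digests": dict(self.input_digests),
            "timestamp": self.timestamp,
            "version": self.version,
        }

    @classmethod
    def for_result(
        cls,
        result: HotspotResult,
        command: str = "",
        inputs: Optional[dict] = None,
    ) -> "RunManifest":
        digests = {
            name: file_digest(path) for name, path in (inputs or {}).items()
        }
        return cls(
            command=command or " ".join(sys.argv),
            seed=result.seed,
            K=result.K,
            n=result.n,
            region=f"{result.region.start}:{result.region.end}",
            severity_filter=result.severity_filter,
            input_digests=digests,
        )


def write_results(
    result: HotspotResult,
    manifest: RunManifest,
    prefix: Union[str, Path],
) -> tuple[Path, Path]:
    """Write ``PREFIX.results.tsv`` and ``PREFIX.run.json``.

    Column order is stable and floats use a fixed format, so identical runs
    produce byte-identical tables.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv_path = prefix.with_suffix(prefix.suffix + ".results.tsv")
    json_path = prefix.with_suffix(prefix.suffix + ".run.json")
    table = result.table[RESULT_COLUMNS]
    with open(tsv_path, "w") as handle:
        handle.write("\t".join(RESULT_COLUMNS) + "\n")
        for _, row in table.iterrows():
            handle.write(
                f"{row['domain']}\t{row['start']:d}\t{row['end']:d}\t"
                f"{row['L']:d}\t{row['D']:d}\t{row['E_hat']:.6g}\t"
                f"{row['E_analytic']:.6g}\t{row['p_raw']:.6g}\t"
                f"{row['p_bonferroni']:.6g}\t{row['stars']}\n"
            )
    with open(json_path, "w") as handle:
        json.dump(manifest.to_dict(), handle, indent=2, sort_keys=True)
        handle.write("\n")
    return tsv_path, json_path


def read_results(prefix: Union[str, Path]) -> tuple[pd.DataFrame, dict]:
    """Read back a results table and its manifest."""
    prefix = Path(prefix)
    table = pd.read_csv(
        prefix.with_suffix(prefix.suffix + ".results.tsv"),
        sep="\t",
        keep_default_na=False,
    )
    with open(prefix.with_suffix(prefix.suffix + ".run.json")) as handle:
        manifest = json.load(handle)
    return table, manifest


def plot_lollipop(
    catalog: VariantCatalog,
    dmap: DomainMap,
    sequence: Optional[ProteinSequence] = None,
    path: Union[str, Path, None] = None,
    title: str = "",
) -> plt.Figure:
    """Lollipop plot of mutation positions over the primary structure.

    Stems rise at mutated positions with height equal to mutation
    multiplicity, colored by the most severe class at that position; domain
    bands are drawn beneath the axis. Records without a position are skipped.
    """
    severity_rank = {
        Severity.SILENT_CONTROL: 0,
        Severity.NONPATHOGENIC: 1,
        Severity.MILD_BFNE: 2,
        Severity.UNCERTAIN: 3,
        Severity.SEVERE_EE: 4,
    }
    counts: dict[int, int] = {}
    worst: dict[int, Severity] = {}
    for rec in catalog:
        if rec.variant_class not in POSITIONAL_CLASSES or rec.position is None:
            continue
        if not dmap.region.contains(rec.position):
            continue
        counts[rec.position] = counts.get(rec.position, 0) + 1
        prev = worst.get(rec.position)
        if prev is None or severity_rank[rec.severity] > severity_rank[prev]:
            worst[rec.position] = rec.severity
    fig, ax = plt.subplots(figsize=(11, 3.2))
    region = dmap.region
    for pos in sorted(counts):
        color = SEVERITY_COLORS[worst[pos]]
        ax.plot([pos, pos], [0, counts[pos]], color=color, lw=1.2, zorder=2)
        ax.plot(pos, counts[pos], "o", color=color, ms=4, zorder=3)
    band_y, band_h = -0.9, 0.7
    for dom in dmap.domains:
        ax.add_patch(
            plt.Rectangle(
                (dom.start - 0.5, band_y),
                dom.length,
                band_h,
                facecolor="#cbd5e0",
                edgecolor="#4a5568",
                lw=0.6,
                zorder=1,
            )
        )
        ax.text(
            (dom.start + dom.end) / 2,
            band_y + band_h / 2,
            dom.name,
            ha="center",
            va="center",
            fontsize=5.5,
            rotation=0 if dom.length > region.length / 30 else 90,
        )
    ax.set_xlim(region.start - 5, region.end + 5)
    top = max(counts.values(), default=1)
    ax.set_ylim(band_y - 0.3, top + 1)
    ax.set_xlabel("residue position")
    ax.set_ylabel("mutation count")
    ax.spines[["top", "right"]].set_visible(False)
    if title:
        ax.set_title(title, fontsize=10)
    handles = [
        plt.Line2D([], [], color=c, marker="o", ls="-", label=s.value)
        for s, c in SEVERITY_COLORS.items()
        if any(w is s for w in worst.values())
    ]
    if handles:
        ax.legend(handles=handles, fontsize=6, loc="upper left", frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
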