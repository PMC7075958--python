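"""Bundled synthetic demonstration data.

A Kv7.2-style protein of 872 residues with two domain annotations (a
14-domain full-length map and a 9-domain C-terminal-tail map), a pathogenic
variant catalog of 194 records, and a control catalog of 130 silent plus 25
common nonpathogenic missense variants.

All of it is SYNTHETIC: the sequence is randomly generated (with the
landmark residues L203, L268, K552, R553 and the initiator methionine
pinned), the domain boundaries follow the field-standard Kv7.2 topology
(S1-S6, pore loop, C-terminal helices A-D), and the variant positions were
constructed so that the catalog's class and severity composition and its
clustering behaviour emulate a real compiled epilepsy-variant table. It is a
demonstration and test fixture, not clinical data. The generating script is
``scripts/make_demo_data.py``.
"""

from __future__ import annotations

from importlib import resources

from .catalog import VariantCatalog
from .domains import AnalysisRegion, DomainMap, ProteinSequence, load_domain_map

#: the C-terminal tail begins immediately after S6 in the bundled annotation
CTERM_START = 313


def _data_path(name: str):
    return resources.files("mhf.data").joinpath(name)


def load_demo_sequence() -> ProteinSequence:
    """The synthetic 872-residue Kv7.2-style reference sequence."""
    with resources.as_file(_data_path("kcnq2_synthetic.fasta")) as path:
        return ProteinSequence.from_fasta(path)


def load_demo_domains(which: str = "full") -> DomainMap:
    """Bundled domain maps: ``"full"`` (J = 14, region 1..872) or
    ``"cterm"`` (J = 9, region 313..872)."""
    seq = load_demo_sequence()
    if which == "full":
        region = AnalysisRegion.full(seq)
        name = "kcnq2_synthetic_domains_full.tsv"
    elif which == "cterm":
        region = AnalysisRegion(CTERM_START, seq.length)
        name = "kcnq2_synthetic_domains_cterm.tsv"
    else:
        raise ValueError(f"unknown domain map {which!r}; use 'full' or 'cterm'")
    with resources.as_file(_data_path(name)) as path:
        return load_domain_map(path, region)


def load_demo_catalog(validate: bool = True) -> VariantCatalog:
    """The synthetic pathogenic catalog (194 records)."""
    seq = load_demo_sequence() if validate else None
    with resources.as_file(_data_path("kcnq2_synthetic_catalog.tsv")) as path:
        return VariantCatalog.from_tsv(path, sequence=seq)


def load_demo_controls(validate: bool = True) -> VariantCatalog:
    """The synthetic control catalog (130 silent + 25 nonpathogenic)."""
    seq = load_demo_sequence() if validate else None
    with resources.as_file(_data_path("kcnq2_synthetic_controls.tsv")) as path:
        return VariantCatalog.from_tsv(path, sequence=seq)
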