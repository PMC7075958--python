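"""Regenerate the bundled synthetic demonstration data (src/mhf/data/).

Deterministic. The synthetic Kv7.2-style fixture emulates a compiled
epilepsy-variant table: 194 pathogenic records whose class composition is
10 gene deletions, 17 splice-site, 10 nonsense, 25 frameshift,
2 non-initiation, 126 missense and 4 single-residue deletions, plus a
control catalog of 130 silent and 25 common nonpathogenic missense
variants. Single-amino-acid variants are placed so that S4, the pore loop
and S6 are strongly enriched (and, within the C-terminal tail, helix B and
the helix B-C linker), while controls are laid down evenly.

Run from the repository root:  python scripts/make_demo_data.py
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

DATA = ROOT / "src" / "mhf" / "data"

SEQ_LENGTH = 872
SEED = 7
AA = list("ACDEFGHIKLMNPQRSTVWY")

# landmark residues pinned into the random sequence (1-based -> one-letter)
PINNED = {1: "M", 203: "L", 268: "L", 552: "K", 553: "R", 560: "R"}

FULL_DOMAINS = [
    ("S1", 92, 112),
    ("S2", 123, 143),
    ("S3", 167, 187),
    ("S4", 196, 218),
    ("S5", 232, 252),
    ("pore_loop", 265, 285),
    ("S6", 292, 312),
    ("pre_helix_A", 313, 334),
    ("helix_A", 335, 365),
    ("helix_A_B_linker", 366, 534),
    ("helix_B", 535, 557),
    ("helix_B_C_linker", 558, 588),
    ("helix_C", 589, 620),
    ("helix_D", 828, 858),
]

CTERM_DOMAINS = [
    ("pre_helix_A", 313, 334),
    ("helix_A", 335, 365),
    ("helix_A_B_linker", 366, 534),
    ("helix_B", 535, 557),
    ("helix_B_C_linker", 558, 588),
    ("helix_C", 589, 620),
    ("helix_C_D_linker", 621, 827),
    ("helix_D", 828, 858),
    ("distal_C_terminus", 859, 872),
]

# per-domain allocation of the 130 single-amino-acid pathogenic variants:
# (domain span, [(severity, count), ...], forced positions)
SINGLE_AA_PLAN = [
    ((196, 218), [("severe_ee", 13), ("uncertain", 3), ("mild_bfne", 2)], [203]),
    ((265, 285), [("severe_ee", 12), ("uncertain", 2), ("mild_bfne", 2)], [268]),
    ((292, 312), [("severe_ee", 11), ("uncertain", 2), ("mild_bfne", 2)], []),
    ((92, 112), [("mild_bfne", 2), ("uncertain", 2)], []),
    ((123, 143), [("mild_bfne", 2), ("uncertain", 2)], []),
    ((167, 187), [("mild_bfne", 2), ("uncertain", 2)], []),
    ((232, 252), [("mild_bfne", 2), ("uncertain", 2)], []),
    ((313, 334), [("mild_bfne", 2), ("uncertain", 2)], []),
    ((335, 365), [("severe_ee", 1), ("mild_bfne", 4), ("uncertain", 3)], []),
    ((366, 534), [("severe_ee", 2), ("mild_bfne", 4), ("uncertain", 6)], []),
    ((535, 557), [("severe_ee", 9), ("mild_bfne", 1), ("uncertain", 2)], [552, 553]),
    ((558, 588), [("severe_ee", 9), ("uncertain", 2)], [560]),
    ((589, 620), [("mild_bfne", 1), ("uncertain", 2)], []),
    ((828, 858), [("mild_bfne", 1), ("uncertain", 1)], []),
]

# inter-domain scatter: (position, severity)
SCATTER = [
    (20, "mild_bfne"), (45, "severe_ee"), (60, "mild_bfne"),
    (70, "severe_ee"), (85, "mild_bfne"),
    (115, "mild_bfne"), (150, "mild_bfne"), (190, "uncertain"),
    (225, "uncertain"),
    (650, "uncertain"), (700, "uncertain"), (750, "uncertain"),
    (865, "uncertain"),
]

# emission-order indices converted to single-residue deletions
# (two in the helix A-B linker, one in helix C, one in helix D)
DELETION_POSITIONS_INDEX = {80, 85, 113, 116}

NONSENSE = [
    (110, "severe_ee"), (140, "severe_ee"), (175, "uncertain"),
    (213, "severe_ee"), (240, "severe_ee"), (270, "severe_ee"),
    (300, "severe_ee"), (450, "uncertain"), (550, "severe_ee"),
    (600, "mild_bfne"),
]


def make_sequence(rng: np.random.Generator) -> str:
    letters = rng.choice(AA, size=SEQ_LENGTH)
    for pos, aa in PINNED.items():
        letters[pos - 1] = aa
    return "".join(letters)


def even_positions(start: int, end: int, count: int, forced: list[int]) -> list[int]:
    """count distinct positions in [start, end], evenly spread, including forced."""
    span = end - start + 1
    grid = [start + int((i + 0.5) * span / count) for i in range(count)]
    grid = [min(p, end) for p in grid]
    positions = list(dict.fromkeys(grid))
    for f in forced:
        if f not in positions:
            # replace the nearest non-forced grid point
            nearest = min(
                (p for p in positions if p not in forced),
                key=lambda p: abs(p - f),
            )
            positions[positions.index(nearest)] = f
    # top up if rounding collapsed any duplicates
    candidate = start
    while len(positions) < count:
        if candidate not in positions:
            positions.append(candidate)
        candidate += 1
    return sorted(positions[:count])


def alt_for(ref: str, pos: int) -> str:
    explicit = {203: "P", 268: "F", 552: "T", 553: "L", 560: "W"}
    if pos in explicit:
        return explicit[pos]
    i = AA.index(ref)
    return AA[(i + 1 + pos) % len(AA)] if AA[(i + 1 + pos) % len(AA)] != ref else AA[(i + 2 + pos) % len(AA)]


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    residues = make_sequence(rng)

    header = (
        "# SYNTHETIC demonstration data; generated by scripts/make_demo_data.py\n"
    )

    with open(DATA / "kcnq2_synthetic.fasta", "w") as fh:
        fh.write(">KCNQ2_SYNTHETIC_DEMO synthetic Kv7.2-style reference, 872 aa\n")
        for i in range(0, SEQ_LENGTH, 60):
            fh.write(residues[i : i + 60] + "\n")

    for name, domains in (
        ("kcnq2_synthetic_domains_full.tsv", FULL_DOMAINS),
        ("kcnq2_synthetic_domains_cterm.tsv", CTERM_DOMAINS),
    ):
        with open(DATA / name, "w") as fh:
            fh.write(header)
            fh.write("name\tstart\tend\n")
            for dom, s, e in domains:
                fh.write(f"{dom}\t{s}\t{e}\n")

    # --- pathogenic catalog -------------------------------------------------
    rows = []  # (variant, class, severity, freq, source)
    single_aa = []  # (position, severity)
    for (start, end), severities, forced in SINGLE_AA_PLAN:
        count = sum(c for _, c in severities)
        positions = even_positions(start, end, count, forced)
        labels = [s for s, c in severities for _ in range(c)]
        # put forced positions first so they pick up the leading severity class
        ordered = forced + [p for p in positions if p not in forced]
        single_aa.extend(zip(ordered, labels))
    single_aa.extend(SCATTER)
    assert len(single_aa) == 130, len(single_aa)

    for i, (pos, severity) in enumerate(single_aa):
        ref = residues[pos - 1]
        if i in DELETION_POSITIONS_INDEX:
            rows.append((f"{ref}{pos}del", "single_aa_deletion", severity, "", "demo"))
        else:
            alt = alt_for(ref, pos)
            rows.append((f"{ref}{pos}{alt}", "missense", severity, "", "demo"))

    for pos, severity in NONSENSE:
        ref = residues[pos - 1]
        rows.append((f"{ref}{pos}*", "nonsense", severity, "", "demo"))

    fs_sev = ["severe_ee"] * 12 + ["uncertain"] * 8 + ["mild_bfne"] * 5
    for i, severity in enumerate(fs_sev):
        rows.append((f"fs_{i + 1:02d}", "frameshift", severity, "", "demo"))
    sp_sev = ["severe_ee"] * 6 + ["uncertain"] * 6 + ["mild_bfne"] * 5
    for i, severity in enumerate(sp_sev):
        rows.append((f"splice_{i + 1:02d}", "splice_site", severity, "", "demo"))
    gd_sev = ["severe_ee"] * 5 + ["uncertain"] * 3 + ["mild_bfne"] * 2
    for i, severity in enumerate(gd_sev):
        rows.append((f"gene_del_{i + 1:02d}", "gene_deletion", severity, "", "demo"))
    rows.append(("M1V", "non_initiation", "uncertain", "", "demo"))
    rows.append(("M1T", "non_initiation", "uncertain", "", "demo"))
    assert len(rows) == 194, len(rows)

    with open(DATA / "kcnq2_synthetic_catalog.tsv", "w") as fh:
        fh.write(header)
        fh.write("variant\tclass\tseverity\tallele_freq_pct\tsource\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")

    # --- control catalog ----------------------------------------------------
    ctrl_rows = []
    silent_pos = sorted(
        {int(round(p)) for p in np.linspace(4, 869, 130)}
    )
    assert len(silent_pos) == 130
    freqs = np.geomspace(0.0017, 19.0, 130)
    for pos, freq in zip(silent_pos, freqs):
        ref = residues[pos - 1]
        ctrl_rows.append(
            (f"{ref}{pos}{ref}", "silent", "silent_control", f"{freq:.4g}", "demo")
        )
    nonpath_pos = sorted({int(round(p)) for p in np.linspace(9, 863, 25)})
    assert len(nonpath_pos) == 25
    freqs = np.geomspace(0.01, 5.0, 25)
    for pos, freq in zip(nonpath_pos, freqs):
        ref = residues[pos - 1]
        alt = alt_for(ref, pos)
        ctrl_rows.append(
            (f"{ref}{pos}{alt}", "missense", "nonpathogenic", f"{freq:.4g}", "demo")
        )
    with open(DATA / "kcnq2_synthetic_controls.tsv", "w") as fh:
        fh.write(header)
        fh.write("variant\tclass\tseverity\tallele_freq_pct\tsource\n")
        for row in ctrl_rows:
            fh.write("\t".join(row) + "\n")

    print("wrote synthetic demo data to", DATA)


if __name__ == "__main__":
    main()
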