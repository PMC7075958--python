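"""Is hotspot membership associated with clinical severity?

Cross-tabulates the single-amino-acid pathogenic variants by (inside a
hotspot domain?) x (severe clinical class?) and applies Fisher's exact test,
computed exactly from the hypergeometric distribution. A small p-value means
severe variants are over-represented inside the hotspot domains relative to
mild/uncertain variants.
"""

from mhf import build_contingency, datasets, fisher_exact_2x2

catalog = datasets.load_demo_catalog()
full_map = datasets.load_demo_domains("full")
hotspots = ["S4", "pore_loop", "S6", "helix_B", "helix_B_C_linker"]

table = build_contingency(catalog, full_map, hotspots)
(a, b), (c, d) = table.as_rows()
print("                 severe   other-pathogenic")
print(f"in hotspots      {a:6d}   {b:6d}")
print(f"elsewhere        {c:6d}   {d:6d}")
print(f"\ntwo-sided Fisher exact p = {fisher_exact_2x2(table):.3g}")
print(f"one-sided (greater)    p = {fisher_exact_2x2(table, 'one-sided-greater'):.3g}")
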