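# mhf — Mutation Hotspot Finder

A library and command-line tool for asking a simple question about disease
variants in a protein: **do single-amino-acid mutations concentrate in
particular functional domains more than chance placement would allow?**

The motivating system is the neuronal voltage-gated potassium channel
subunit Kv7.2 (KCNQ2), where epilepsy-associated missense variants of
differing clinical severity (benign familial neonatal epilepsy through
epileptic encephalopathy) are scattered along an 872-residue protein with
well-annotated domains (transmembrane segments S1–S6, the pore loop, and
C-terminal helices A–D). The same machinery applies to any protein with a
variant catalog and a domain annotation.

## The statistic

Let `S` be the multiset of observed single-amino-acid mutation positions in
an analysis region `X` of length `L_X` (the whole protein or a sub-range such
as a C-terminal tail), with `|S|` counting unique variants — distinct
substitutions at one codon count separately. For each annotated domain `j`
with length `L_j`, `D_j` is the number of mutations falling inside it.

Under the null hypothesis that mutations are equally likely at every residue
of `X`, the test bootstraps `K = 10,000` sets `S̃(k)` of `|S|` positions drawn
uniformly with replacement from `X`, tallies per-domain counts `D̃_j(k)`, and
reports

- the empirical expectation `Ê_j = (1/K) Σ_k D̃_j(k)`,
- the right-tailed add-one empirical p-value
  `P̂_j = (1 + Σ_k I[D̃_j(k) ≥ D_j]) / (K + 1)`,
- Bonferroni-adjusted p-values `min(1, J·P̂_j)` over the `J` domains tested.

The marginal null distribution of each `D̃_j` is Binomial(`|S|`, `L_j/L_X`),
and an exact binomial tail is built in as an analytic oracle; the
test suite verifies that the bootstrap agrees with it to Monte-Carlo error.
Truncating variant classes (nonsense, frameshift), splice-site and
gene-level events are excluded from `S` because a per-residue null is
meaningless for them; missense variants at the primary start codon and
non-initiation variants are likewise excluded.

Around the core test the package provides:

- **Variant catalog handling** — parsing of one-letter (`L203P`, `K552del`,
  `R213*`) and three-letter HGVS-p (`p.Leu203Pro`) labels, a variant-class /
  severity taxonomy, and the filter producing `S`.
- **Severity association** — Fisher's exact test (exact integer
  hypergeometric arithmetic, minimum-likelihood two-sided convention)
  crossing hotspot membership against the severe clinical class.
- **Synthetic data** — uniform-null and mixture-alternative catalog
  generators with a calibration harness measuring type-I error and power.
- **Voltage-clamp analysis equations** — leak subtraction, current density,
  normalized conductance, the activation Boltzmann fit
  `G/Gmax = 1/(1 + exp((V_half − V)/k))`, mono-exponential activation τ, and
  the 10-s current-decay ratio used to index PIP2-depletion sensitivity.
- **Reporting** — TSV/JSON results with reproducibility manifests and a
  lollipop plot of mutations over the primary structure.

The bundled demonstration data (`mhf.datasets`) are **synthetic**: a
generated Kv7.2-style sequence and a variant table whose composition
(194 records; 126 missense; 130 single-amino-acid pathogenic variants) and
clustering behaviour emulate a real compiled epilepsy-variant catalog. See
`docs/methods.md` for exactly what is and is not emulated.

## Worked example

```bash
python examples/hotspot_scan.py
```

prints (abridged):

```
|S| = 130 single-amino-acid variants, K = 10000

          domain   L  D   E_hat    p_raw  p_bonferroni stars
              S1  21  4  3.1381 0.387661      1.000000
              S4  23 18  3.4448 0.000100      0.001400   ***
       pore_loop  21 16  3.1460 0.000100      0.001400   ***
              S6  21 15  3.1180 0.000100      0.001400   ***
         helix_B  23 12  3.4371 0.000100      0.001400   ***
helix_B_C_linker  31 11  4.6319 0.007999      0.111989
...
hotspots (Bonferroni p <= 0.05): S4, pore_loop, S6, helix_B
```

Reading: S4 contains 18 observed variants where uniform placement predicts
about 3.4; none of 10,000 bootstrap sets reached 18, so the raw p-value
takes its floor `1/(K+1) ≈ 1e-4` and survives the 14-fold Bonferroni
correction (`***` = p < 0.005). S1, with 4 variants against 3.1 expected, is
consistent with the null. Restricting the analysis region to the C-terminal
tail (second half of the example) re-tests the tail domains against a null
confined to the tail, where helix B and the helix B-C linker emerge.

Other examples: `severity_association.py` (hotspot membership vs severe
class, Fisher exact p ≈ 7e-15 on the fixture), `calibration.py` (type-I
error and power of the test on simulated catalogs), `boltzmann_fit.py` and
`vsp_decay.py` (parameter recovery for the electrophysiology equations).

The same analyses are available from the shell:

```bash
mhf run --catalog catalog.tsv --domains domains.tsv --fasta protein.fasta \
    --iterations 10000 --seed 1 --out scan
mhf assoc --catalog catalog.tsv --domains domains.tsv --fasta protein.fasta \
    --hotspots S4,pore_loop,S6 --out assoc.json
```

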