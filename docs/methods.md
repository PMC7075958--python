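# Methods

## The hotspot model and its assumptions

The test treats a protein analysis region `X` (residues `start..end`,
length `L_X`) as the sampling space and asks, for each annotated functional
domain `j` of length `L_j`, whether the observed count `D_j` of
single-amino-acid variants inside it is compatible with uniform placement.
The null is deliberately minimal: every residue of `X` is equally likely to
be mutated, independently across variants. No codon-level mutability
weighting (trinucleotide context, CpG transitions), no gene-wide constraint
scores, and no phylogenetic conservation enter the null; the test therefore
detects *any* departure from per-residue uniformity concentrated in a
domain, whether driven by functional selection or by sequence-level
mutability. That is the appropriate reading of a "hotspot" here.

Sampling is uniform **with replacement** (a bootstrap): several variants may
land on one residue, mirroring the data, where distinct substitutions at one
codon are distinct variants. A without-replacement variant is available
behind a flag (`bootstrap_null(..., replace=False)`) for sensitivity
analysis only.

Only variant classes for which a per-residue null makes sense enter the
mutation set `S`: missense substitutions and single-residue deletions
(and, on the control pathway, silent substitutions). Nonsense and
frameshift variants truncate every downstream domain, splice-site and
gene-deletion events have no single protein coordinate, and non-initiation
variants (including missense at the primary start codon) abolish the
protein rather than perturb a domain; all are excluded by the input filter.
Identical (position, ref, alt) duplicates collapse to one record.

## P-values and multiplicity

Per domain the test is right-tailed with the add-one empirical form

    P̂_j = (1 + #{k : D̃_j(k) ≥ D_j}) / (K + 1),

which ranges over `[1/(K+1), 1]` and is super-uniform under the null
(P(P̂ ≤ α) ≤ α), so the test is conservative by construction. The
documented convention resolves an ambiguity in how the add-one correction
is sometimes written: placing the `+1` inside the sum over `k` would make
the expression identically ≈ 1 and is rejected as a notational slip; the
form above is the standard permutation-test estimator consistent with a
`(K+1)` denominator.

Raw p-values are Bonferroni-multiplied by the number of domains `J` tested
*in that analysis* (14 for the bundled full-length map, 9 for the
C-terminal map) and capped at 1. The smallest attainable adjusted p is
therefore `J/(K+1)`; with `K = 10,000` and `J = 14` that is ≈ 0.0014, below
the strictest reporting threshold (0.005). Significance stars follow the
convention `*** < 0.005`, `** < 0.01`, `* < 0.05` (strict inequalities).

Reproducibility: all draws come from one `numpy` Generator seeded with the
run's master seed and consumed row-major, so results are bit-stable for a
given (seed, K, n, region) regardless of internal chunking. Calibration
replicates use `SeedSequence.spawn` substreams.

## The analytic oracle

Because null positions are i.i.d. uniform, each `D̃_j` is marginally
Binomial(`n`, `L_j/L_X`). `exact_binomial_pvalue` computes the exact right
tail and serves as an independent check: tests require the bootstrap p at
`K = 10,000` to match `(1 + K·b)/(K + 1)` within 3 Monte-Carlo standard
errors (`b` the binomial tail) across randomized configurations. The oracle
never replaces the bootstrap in the analysis path.

## Severity association

`build_contingency` crosses hotspot membership (inside any of a named set
of domains vs elsewhere) against clinical severity (severe vs
mild ∪ uncertain by default) at the level of individual variants. The
stratification is exposed as parameters rather than hard-coded, because
other defensible unit choices exist (residues rather than variants,
different hotspot sets, different severity splits). `fisher_exact_2x2`
computes the exact hypergeometric test with integer arithmetic — all tables
at fixed margins share the denominator `C(N, col1)`, so two-sided
tie handling (minimum-likelihood convention, the dominant convention of
standard statistical software) reduces to integer comparisons and the
p-value is exact up to one final float conversion. Tests verify exhaustive
agreement with a brute-force enumeration oracle for all tables with total
≤ 30 and cross-check against an independent library implementation.

## Synthetic data: what it emulates and what it does not

`simulate_null_set` realizes the null exactly. `simulate_clustered_catalog`
draws each variant from a mixture: with probability `π` it lands uniformly
inside a designated hotspot domain (hotspot chosen proportional to length,
so `π` is interpretable as total excess hotspot mass and the expected
hotspot count has the closed form `n(π + (1 − π)·L_hot/L_X)`), otherwise
uniformly over the region. Severity labels are severe with probability
`ρ = 0.7` inside hotspots and `0.3` elsewhere (defaults chosen to resemble
a catalog in which roughly half of single-amino-acid variants are severe
and severity concentrates in hotspots; non-severe labels split evenly
between mild and uncertain).

The generators emulate *placement and labeling only*. They do not emulate
ascertainment bias in variant reporting, recurrent mutation at CpG sites,
codon structure, linkage between variants, or uncertainty in clinical
classification. Passing calibration therefore shows that the statistic
behaves correctly under its own null and a clean clustered alternative —
not that real catalogs satisfy those conditions.

### The bundled fixture

`mhf/data/` ships a fully synthetic Kv7.2-style demonstration dataset,
regenerated deterministically by `scripts/make_demo_data.py`: a random
872-residue sequence with landmark residues pinned (M1, L203, L268, K552,
R553, R560), domain maps following the field-standard Kv7.2 topology
(S1–S6 with the pore loop between S5 and S6; C-terminal pre-helix A,
helices A–D and their linkers; 14 domains full-length, 9 tiling the
C-terminal tail), a 194-record pathogenic catalog (126 missense, 4
single-residue deletions, 10 nonsense, 25 frameshift, 17 splice-site, 10
gene deletions, 2 non-initiation; 130 variants surviving the input filter)
and a control catalog (130 evenly spaced silent variants with allele
frequencies spanning 0.0017–19%, and 25 common nonpathogenic missense with
frequency ≥ 0.01%). Pathogenic positions are placed so that S4, the pore
loop and S6 are strongly enriched, with additional severe-variant
concentration in helix B and the helix B-C linker that becomes significant
in the C-terminal sub-analysis; controls are laid down near-uniformly and
cluster nowhere. The fixture is a demonstration and test vehicle — its
per-variant entries are not clinical observations.

## Electrophysiology equations

Conventions that the data do not themselves pin down are fixed as follows:

- **Boltzmann parenthesization.** The activation fit is
  `G/Gmax = 1/(1 + exp((V_half − V)/k))` with `k > 0` in mV — the standard
  activation form; the alternative literal reading of the loosely-bracketed
  formula (dividing an exponential of a voltage difference by `k`) is
  dimensionally incoherent and is not implemented.
- **Conductance source.** `G(V) = I_peak(V)/(V − V_rev)` from steady-state
  peak currents with a supplied reversal potential; tail-current analysis
  is out of scope. Peaks are signed at the maximal amplitude so steps below
  the reversal potential (inward current) still yield positive conductance.
  Steps at `V = V_rev` are excluded with a warning (zero driving force).
- **Activation τ.** One mono-exponential `I(t) = A(1 − exp(−t/τ)) + C`
  fitted from stimulus onset to the peak, initialized at the 63%-rise time.
  A convention, documented as such: multi-exponential activation is not
  resolved.
- **Decay ratio.** `I(t = 10 s)/I_peak` per voltage step; percent decay is
  `(1 − ratio)·100`. A non-positive peak raises an error rather than
  returning an undefined ratio.

Degenerate inputs (flat traces, < 4 conductance points, non-convergent
fits) raise `FitError`/`ProtocolError` rather than returning silently bad
estimates. The synthetic trace generator produces ideal currents
(Boltzmann-gated, mono-exponentially activating, optional ohmic leak and
Gaussian noise); it omits capacitive transients, series-resistance error
and rundown, so parameter-recovery results bound estimator error only under
those idealizations. Published wet-lab values for this channel (e.g. a
wild-type half-activation near −27 mV, maximal 10-s decay around 53% at
+100 mV) are context for choosing realistic synthetic parameters, not
quantities this package can reproduce from first principles.

## Problem sizes and numerical choices

Defaults follow the study conditions the package is built around:
`K = 10,000` bootstrap iterations, `n = 130` variants, `α = 0.05` after
correction. The calibration harness uses `R = 500` null replicates at
`K = 2,000` (the type-I rate estimate has SE ≈ 0.01, and super-uniformity
holds at any K) and `R = 150` power replicates at `K = 10,000` (needed so
the minimal adjusted p, `J/(K+1)`, can fall below 0.005). The
oracle-equivalence check uses 100 randomized configurations at
`K = 10,000`. These sizes were chosen once as a balance between estimate
stability and desk-scale runtime and are stated wherever reported.

## Known limitations

- The uniform null ignores mutational heterogeneity along the gene; domains
  enriched for hypermutable codons can appear as hotspots without
  functional cause.
- Bonferroni over pre-specified domains is conservative and tests only the
  annotated intervals; clusters straddling domain boundaries or in
  unannotated linkers are invisible by design (unannotated residues stay in
  the sampling space but carry no hypothesis).
- The severity association inherits whatever biases the severity labels
  carry and does not model ordinal severity or covariates.
- HGVS parsing covers protein-level substitution/deletion grammars only; no
  cDNA/genomic notation, no isoform coordinate lifting — catalogs must be
  pre-harmonized to the reference numbering.
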