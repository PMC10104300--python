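# Methods

## Conservation model

A multiple sequence alignment is analysed with respect to one reference
sequence: columns where the reference holds a gap are removed, and the
remaining columns are numbered 1..L along the ungapped reference. This
discards insertion information relative to the reference but makes every
per-site quantity directly addressable on the reference protein and its
crystal structure, which share the numbering (e.g. Arg120, Ala247, Arg282
in GDAP1).

Per-site conservation is the Shannon entropy of the column's amino-acid
frequency distribution with a base-20 logarithm,
S = −Σ p_j log20 p_j, which normalizes the scale to [0, 1] for a
20-letter alphabet: S = 0 iff exactly one residue type is observed, S = 1
iff all 20 types are equally frequent. Gaps and ambiguity letters
(B, Z, X, U, O) are treated as missing data — excluded from both the
numerator and denominator of the frequencies — but every analysed row
counts in the denominator of the site's non-gap fraction, which acts as a
coverage filter when reporting conserved sites (a site can only be called
conserved if enough sequences actually have a residue there). Sites with
no observed residues are undefined (NaN), never 0, since S = 0 claims
full conservation.

Default thresholds: S ≤ 0.1 "highly conserved" within a subfamily,
S < 0.2 "conserved" for very diverse sets spanning a whole superfamily,
coverage > 0.7. All are configurable.

## Kullback-Leibler divergence between subfamilies

For two groups over the same projected alignment, each site yields
D_KL(p‖q) = Σ p_j ln(p_j/q_j), computed in both directions because KL is
asymmetric; the natural logarithm is used here (the base-20 normalization
is specific to the entropy scale, and the two scales are deliberately not
harmonized). Raw group counts are smoothed by adding a pseudocount
(default 0.5, a Jeffreys-style prior) to each of the 20 counts before
normalizing; without smoothing the divergence is infinite wherever the
reference group observes a residue type the other group never does, which
is common at exactly the sites of interest. With smoothing, KL ≥ 0 always
(Gibbs' inequality) and KL = 0 iff the smoothed distributions coincide.

The divergence report ranks sites by max(KL_1, KL_2) and flags sites that
are conserved (S below threshold) in at least one group — the candidate
specificity-determining positions. Modal residues per group are computed
over all characters *including* gaps, so a site where one subfamily mostly
has a deletion shows '-' as its modal character; an indel difference
between subfamilies is informative and should not be masked.

Consensus and modal ties break alphabetically by one-letter code, making
all outputs deterministic.

## Representative selection

The pairwise distance between two aligned sequences is 1 − fractional
identity over columns where both have a residue; pairs with no mutually
non-gap columns get distance 1. Reduction to k representatives repeatedly
finds the globally closest remaining pair and removes one member until k
survive. Which member to remove is genuinely underdetermined by the
"most even spread" goal; the implemented rule removes the member whose
next-nearest remaining neighbour (excluding the pair partner) is closer —
i.e. the member in the denser region — so isolated sequences, which carry
unique information, are kept. Distance and neighbour ties break
lexicographically by id, removing the later id. The procedure is fully
deterministic and, because smaller k is reached by continuing the same
removal trajectory, the minimum retained pairwise distance is
non-decreasing as k decreases. On small clustered instances the greedy
result attains the exhaustive-search optimum of the minimum retained
distance (verified by enumeration in the test suite); no optimality
guarantee is claimed in general.

Merging reduced sets treats two records as duplicates when they share an
id or an identical residue string, keeping the first occurrence.

## Structure analyses

**Superposition and deviation.** Variant structures are superposed onto
wild type by least-squares rigid fit (proper rotation) on shared Cα atoms;
the per-residue deviation profile is the Cα-Cα distance after the fit.
The fit set defaults to all shared Cα; restricting the *report* to a
subset (e.g. residues in the core hydrogen-bonding network) does not
change the fit. Deviations use Cα only; side-chain movement is out of
scope.

**Polar contacts.** Crystal structures carry no hydrogens, so hydrogen
bonds are detected on heavy atoms: a donor N/O (identified from residue
chemistry) within `hbond_max` (default 3.5 Å) of an acceptor N/O, with
the antecedent-donor-acceptor angle at least `angle_min` (default 90°) as
a proxy for plausible hydrogen geometry; when the antecedent atom is
absent from the model the angle test is skipped rather than failing the
contact. Ionic contacts are charged side-chain nitrogens of Arg/Lys/His
within `ionic_max` (default 4.0 Å) of carboxylate oxygens of Asp/Glu; a
pair satisfying both definitions is labelled ionic once, not
double-counted. By default each residue pair contributes its closest
qualifying atom pair (the residue-pair count is the headline number); an
all-pairs mode and the atom-level count are always available because
published contact counts may be quoted at either granularity. His is
treated as both donor and acceptor at ND1/NE2 and as positively charged,
the permissive convention absent protonation assignment. Because the
geometric criteria behind any published "designated contacts" count are
tool-dependent, `contact_count_grid` reports counts across a cutoff grid
rather than asserting one setting.

**Helix annotations.** Helix residue ranges are curator-supplied config,
not derived from geometry (secondary-structure assignment is out of
scope). The shipped `data/gdap1.toml` encodes ranges consistent with the
residues the structural literature assigns to GDAP1's core helices
(α3 116-131, α6 195-227, α7 247-262, α8 275-290, the α6-α7 loop 236-241)
plus a curated list of CMT missense-mutation sites; both are inputs to
audit, not outputs.

**Conservation painting.** Per-site entropy is written into the B-factor
column (B = 100·S by default, clamped to the PDB field range; residues
without a value get −1 and are listed) so any molecular viewer can colour
the structure by conservation.

**Mutation overlap.** Residues appearing in the contact network, the
mutation list or the conserved-site list are classified as both /
cmt-only / conserved-only / neither; for a focus segment (default the
α6-α7 loop) the residues contacting it are listed with their classes,
exposing whether the segment's interaction partners are evolutionarily
constrained and/or disease-relevant.

## Synthetic data

The generator draws each column's distribution once (explicit vector, or
symmetric Dirichlet with concentration controlling conservation: 0.01
gives near-degenerate columns, 100 near-uniform), then draws rows i.i.d.
and injects gaps independently at a configurable rate. Two-group families
share drawn distributions except at listed divergent sites. All
generators are pure functions of spec + seed, and return their ground
truth (realized distributions, divergent-site keys, displacement
magnitudes).

This emulates exactly the object the estimators target — the per-column
distribution — and nothing more. Real families violate the row-exchange
assumption: sequences are phylogenetically correlated, effective sample
sizes are smaller than row counts, and gap patterns are structured by
indel history rather than i.i.d. Passing recovery tests therefore
demonstrates estimator correctness, not robustness to phylogenetic
sampling bias; no correction for non-independence is attempted, matching
the plain frequency-counting convention of the analysis this package
implements.

Toy structures are ideal poly-alanine helices (rise 1.5 Å, 100° per
residue, Cα radius 2.3 Å, giving consecutive Cα-Cα ≈ 3.8 Å) with backbone
N/CA/C/O placed on idealized tracks; side-chain donors/acceptors for
contact fixtures are placed explicitly by the test code. They exercise
geometry code, not protein energetics.

## Numerical and test-scale choices

- 0·log 0 and 0·ln 0 terms are 0; entropy values are clamped against the
  −0.0 float artefact.
- Superposition uses the closed-form least-squares fit from the structure
  library; equality checks against it in tests allow 1e-6 Å slack for
  accumulated float error, while ground-truth displacement recovery is
  asserted to 1e-3 Å.
- Estimator-recovery tests run at 50/500/5000 rows over 10 Dirichlet(1.0)
  sites; the plug-in entropy estimator's downward bias (~(K−1)/(2n ln 20))
  makes the error decrease predictable at these depths. Divergence
  recovery uses 200 rows per group with 5 disjoint-support divergent
  sites among 25. Representative-selection optimality is enumerated
  exhaustively only for n ≤ 8.
- Greedy selection is O(n³) in the worst case with a vectorized inner
  scan; adequate for the ~10³-sequence sets this workflow targets.

## Known limitations

- Group assignment by annotation substring matching is a pragmatic stand-in
  for curated subfamily membership; mis-annotated database entries
  propagate into the groups.
- Contact chemistry tables cover the 20 standard residues; modified
  residues and ligands are skipped with a log message.
- The reference projection drops reference-gap columns, so
  subfamily-specific insertions are invisible to all per-site reports.
- No statistical significance is attached to entropy or KL values; they
  are descriptive rankings.
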