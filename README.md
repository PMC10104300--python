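# famcons

Family-level sequence conservation and structure-network analysis for
GST-fold proteins, built around the disease protein GDAP1
(ganglioside-induced differentiation-associated protein 1, a mitochondrial
outer-membrane protein with a glutathione-S-transferase-like fold whose
missense mutations cause Charcot-Marie-Tooth neuropathy).

The package is for structural bioinformaticians who have (a) a multiple
sequence alignment of a protein family split into subfamilies by
annotation, and (b) crystal structures of a wild-type protein and point
variants, and who want to connect evolutionary conservation to the residue
interaction networks that hold the fold together.

## What it computes

**Per-site conservation.** For alignment column *i* projected onto a
reference sequence, with amino-acid frequencies *p<sub>j</sub>* over the 20
standard types (gaps and ambiguity codes are missing data),

> *S<sub>i</sub>* = −Σ<sub>j</sub> *p<sub>j</sub>* log<sub>20</sub> *p<sub>j</sub>*

so *S* ranges from 0 (fully conserved) to 1 (uniformly random). Conserved
sites are reported with their non-gap fraction as a coverage filter
(defaults: *S* ≤ 0.1 "highly conserved", *S* < 0.2 "conserved", coverage
> 70%).

**Between-subfamily divergence.** For two groups with per-site
distributions *p* and *q*, the Kullback-Leibler divergence

> *D<sup>KL</sup><sub>i</sub>* = Σ<sub>j</sub> *p<sub>i,j</sub>* ln(*p<sub>i,j</sub>*/*q<sub>i,j</sub>*)

is computed in both directions on pseudocount-smoothed counts, ranking
sites that are conserved within one subfamily but occupied differently in
the other — candidate specificity-determining positions.

**Representative selection.** A sequence set is thinned to *k*
representatives by repeatedly removing one member of the closest remaining
pair in the pairwise identity-distance matrix, keeping the most even
possible spread — the standard data reduction before tree inference.

**Structure analyses.** Rigid least-squares superposition of variant onto
wild-type structures with per-residue Cα deviation profiles;
hydrogen-bond/salt-bridge network extraction between configured core
helices (heavy-atom distance and donor-antecedent angle criteria, since
crystal structures carry no hydrogens); conservation painted into the PDB
B-factor column; and classification of residues by overlap between
disease-mutation sites and conserved sites, including the contacts of a
focus segment such as the GDAP1 α6-α7 loop.

A synthetic-data module generates alignments with known column
distributions, two-group families with injected divergent sites, and ideal
poly-alanine helices with controlled displacements, so every stage is
testable against ground truth without downloads.

## Worked example

Build a synthetic two-group family (200 sequences per group, 25 sites,
shared Dirichlet-drawn column distributions) with divergent residues
injected at sites 3 (Trp vs. Tyr) and 7 (Asp vs. Lys), then rank sites by
bidirectional KL:

```python
import numpy as np
from famcons import synthetic as syn
from famcons.conservation import divergence_profile
from famcons.sequence_io import AMINO_ACIDS

def fixed(r):
    p = np.zeros(20); p[AMINO_ACIDS.index(r)] = 1.0; return p

spec = syn.FamilySpec(n_sequences=200,
                      sites=(syn.SiteSpec(concentration=0.5),) * 25, seed=42)
aln, key = syn.generate_two_groups(
    spec, {3: (fixed("W"), fixed("Y")), 7: (fixed("D"), fixed("K"))})
g1, g2 = aln.rows_of_group("group1"), aln.rows_of_group("group2")
div = divergence_profile(aln, g1, g2, group_labels=("GDAP1", "GST"))
print(div.ranked_table().head(5).to_string(index=False,
      float_format=lambda x: f"{x:.3f}"))
```

```
 res_num  KL_1  KL_2   S_1   S_2 GDAP1 GST  max_kl  conserved_in_one
       3 5.709 5.709 0.000 0.000     W   Y   5.709              True
       7 5.709 5.709 0.000 0.000     D   K   5.709              True
      11 0.145 0.160 0.845 0.851     Y   Y   0.160             False
      13 0.135 0.109 0.872 0.855     I   I   0.135             False
      20 0.098 0.117 0.739 0.772     G   G   0.117             False
```

The two injected sites dominate the ranking (KL_1 = KL_2 = 5.709 is the
maximum achievable with 200 observations per group and pseudocount 0.5:
both smoothed distributions are near-degenerate on different residues, and
each is fully conserved within its group, S = 0). Background sites drawn
from the shared distributions stay an order of magnitude lower. The
`GDAP1`/`GST` columns give each group's modal residue, and
`conserved_in_one` flags sites below the conservation threshold in at
least one group — the signature of a specificity-determining position.

A command-line interface mirrors the library
(`famcons project / entropy / kl / reduce / merge / network / deviation /
paint / simulate / run`); `famcons run --config run.toml` executes the
whole sequence and structure pipeline from one declarative file and writes
a manifest with input checksums for reproducibility.

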