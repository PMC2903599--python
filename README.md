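# jointfold

Comparative prediction of joint RNA secondary structures and RNA–RNA
interactions from two pre-computed multiple sequence alignments.

Many regulatory non-coding RNAs (bacterial sRNAs, snoRNAs, microRNA-like
elements) act by base-pairing with an mRNA or another ncRNA, and conserved
interactions accumulate *compensatory base changes* across species — the
same covariation signal that reveals conserved intra-molecular structure.
`jointfold` exploits this: given an alignment of an ncRNA family and an
alignment of its candidate target region over matched organisms, it
predicts a joint structure — intra-molecular stems of both molecules plus
the inter-molecular duplex — including pseudoknots between the two layers
(e.g. kissing hairpins), which single-pass cofolding cannot represent.

Intended users: RNA bioinformaticians screening candidate sRNA–mRNA (or
ncRNA–ncRNA) pairs for conserved, covarying interaction sites.

## Method

Both steps score consensus base pairs by **expected accuracy** under two
models at once:

* an **evolutionary model**: a phylogenetic SCFG (the lightweight structure
  grammar `S → LS | L`, `L → s | dFd`, `F → dFd | LS`) whose emissions are
  Felsenstein pruning likelihoods of single columns (4-state model) and
  paired columns (16-state dinucleotide model) on a tree estimated from the
  alignment; inside–outside gives posterior pair reliabilities
  `P_ev(i,j)` and single-stranded reliabilities `P_ev(i)`;
* a **thermodynamic model**: a McCaskill-style partition function per
  sequence under a simplified nearest-neighbour energy model, giving pair
  probabilities `P_th(i,j | s)`.

These are combined per alignment column pair,

    R_bp(i,j) = P_ev(i,j) + (β/n) Σ_s P_th(i,j | s)
    R_ss(i)   = α · [ P_ev(i) + (β/n) Σ_s P_th_ss(i | s) ]

and the maximum-expected-accuracy structure is decoded with a
Nussinov-style dynamic program.

**Step 1** fixes, independently per alignment, the *partial structure*
σᵖ: all pairs whose normalised reliability `R_bp/(1+β)` exceeds a cutoff
δ ≥ 0.5 (above ½ of a unit-sum posterior two conflicting pairs can never
both qualify, so the selection is conflict-free by construction).  δ is
raised until the *ensemble probability* of σᵖ — the probability mass of
all structures extending it, `Z_constrained/Z` in each model — reaches a
second threshold γ in the evolutionary model or in every sequence's
thermodynamic ensemble.  Optionally the selected stems are extended
inward/outward while the stem's average reliability stays above δ and the
γ gate keeps passing.

**Step 2** concatenates the two alignments (cofolding convention: the
linker cannot pair, loops containing it are scored as exterior regions,
inter-molecular pairs are exempt from the hairpin minimum) and rescores
under the constraint that all σᵖ positions are single-stranded — the
hierarchical trick that admits pairs crossing the fixed layer.  Raw
constrained probabilities are conditional on σᵖ, so they are multiplied by
the two ensemble probabilities from Step 1, while σᵖ pairs themselves keep
their fixed ensemble probability.  The evolutionary part runs the
constrained phylo-SCFG on the concatenated alignment with three prior-free
linker columns and a joint tree.

**Assembly** decodes the Step-2 reliabilities with σᵖ positions at weight
0, re-adds σᵖ, and reports three bracket layers: `[ ]` constrained pairs,
`( )` new intra-molecular pairs, `< >` inter-molecular pairs.

## Worked example

The package bundles a synthetic-family generator that evolves an alignment
pair down a tree with planted stems and a covarying 6-bp interaction site
(part-1 columns 12–17 pairing part-2 columns 13–18):

```python
from jointfold import SyntheticSpec, generate_pair, write_alignment
pair, truth, tree = generate_pair(SyntheticSpec(seed=0))
write_alignment(pair.aln1, "ncrna.fa")
write_alignment(pair.aln2, "target.fa")
```

```console
$ jointfold ncrna.fa target.fa --delta 0.55 --no-isolated --no-extend
# STOCKHOLM 1.0
...
#=GC SS_joint  .....[[[[.<<<<<<<....]]]].........[[[[.........((.]]]]...)).&.....[[[[...>>>>>>>.(]]]].........[[.)..............]]......
#=GF CC pair table: part i j layer reliability
#=GF PAIR 1 6 25 constrained 1.1094
#=GF PAIR int 12 18 step2-inter 0.6502
#=GF PAIR int 13 17 step2-inter 0.7092
#=GF PAIR int 14 16 step2-inter 0.7080
#=GF PAIR int 15 15 step2-inter 0.7208
...
```

Reading the output: both alignments are joined by `&`; square brackets are
the Step-1 partial structures (here the planted stems, combined
reliability ≈ 1.11 of a maximum of 1+β = 2), angle brackets the predicted
interaction.  The `int i j` rows give part-1 column i pairing part-2
column j — columns 11–19 × 19–11 here, covering the entire planted site —
with their combined Step-2 reliabilities (≈ 0.65–0.72 for the core).  The
interaction crosses the square-bracket stems: a double kissing-hairpin
layout that a nested-only predictor cannot produce.

The same run is available programmatically via
`jointfold.run_pipeline_on_pair(pair, Params(delta=0.55,
allow_isolated=False, extend_stems=False))`.

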