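# Methods

This note documents the models implemented in `jointfold`, the defaults
and why, the numerical choices, and what the synthetic benchmark does and
does not demonstrate.

## Probabilistic models

### Evolutionary model (phylo-SCFG)

Consensus structures of an alignment 𝒜 with tree T are distributed by a
stochastic context-free grammar combined with column-wise substitution
models:

    S → LS | L      L → s | dFd      F → dFd | LS

Unpaired columns emit under a reversible 4-state model, paired column
pairs under a reversible 16-state dinucleotide model, both evaluated by
Felsenstein pruning.  All probabilities are defined over **parse trees**;
the grammar is ambiguous for some structures, and every quantity
(posteriors, ensemble probabilities) sums over parse trees, which the
test-suite's enumeration oracle mirrors exactly.  The grammar implies at
least two columns enclosed by any consensus pair; no additional
consensus-level hairpin minimum is imposed (per-sequence minima live in
the thermodynamic model).

Inside–outside runs in linear space with per-column emission rescaling
(each column's emissions are divided by its unpaired-emission likelihood),
which keeps values in floating-point range for alignments of a few
hundred columns; posterior normalisation per column is asserted to 1e-9.

**Parameters.** Grammar production probabilities are the widely reproduced
values of the published lightweight structure grammar.  The rate matrices
bundled in `assets/pfold_like_params_synthetic.yaml` are **synthetic**
(the original fitted matrices are not redistributed here): an HKY-style
4-state model (κ = 4, mildly A-rich frequencies) and a 16-state model
whose stationary mass concentrates 92% on the six canonical pairs, with
unit exchangeability for single-nucleotide changes, 0.25 for compensatory
double substitutions between canonical pairs, and 0 otherwise; both are
scaled to one expected substitution per site.  Any parameter file in the
same YAML schema can be substituted (`--params-file`).

**Constraints.** Forced-unpaired positions receive zero mass in paired
items; forced-present pairs restrict both positions to each other and
forbid them unpaired; *prior-free* columns (the 3-column linker of the
concatenated alignment) emit probability 1, contribute no
production-probability factor for their unpaired emission, and never pair.
The ensemble probability of a partial structure is
exp(logZ_constrained − logZ_unconstrained).

**Trees.** Neighbour joining on pairwise Jukes–Cantor distances (gaps
excluded pairwise; saturated distances are an error naming the offending
pair), negative NJ branch lengths clamped to 0.  Step 1 uses one tree per
alignment; Step 2 uses a single tree estimated from the concatenated
alignment (linker columns carry no signal).  A user-supplied Newick
overrides all estimates.  Matrix exponentials use eigendecomposition
accepted at 1e-12 reconstruction tolerance, with scipy's
scaling-and-squaring as fallback; t = 0 returns the exact identity.

**Gaps.** Gaps and IUPAC ambiguity codes are missing data (all-ones
partial likelihoods over the compatible states).  A leaf gapped in exactly
one column of a base-paired column pair is treated as missing in both
(symmetric and standard; `pair_gap_policy="marginalise"` keeps the
observed residue instead).

### Thermodynamic model

A deliberately simple nearest-neighbour model authored for this package —
the contract is "a constrained Boltzmann ensemble over nested structures",
not kcal-level agreement with any published parameter set:

| term | form | default |
| --- | --- | --- |
| stacking (6×6 pair steps) | −(strength(outer) + strength(inner)) | GC/CG 1.5, AU/UA 0.9, GU/UG 0.6 kcal/mol |
| hairpin | a + b·size, size ≥ 3 | 4.0 + 0.2·size |
| interior/bulge | a + b·unpaired, ≤ `max_interior` | 1.6 + 0.4·u, cap 30 |
| multiloop | a + b·branches + c·unpaired | 3.4 + 0.4·br + 0.1·u |

RT = 0.61633 kcal/mol (310.15 K).  No dangling ends.  The interior-size
cap is part of the model and is applied identically in the dynamic program
and in the enumeration oracle.  The open chain has energy 0.

**Cofolding.** Two strands are folded as their concatenation with a nick:
the nick cannot pair; any loop whose backbone segments contain the nick is
scored as an exterior-like region (energy 0); base pairs spanning the nick
are exempt from the hairpin minimum; a stack whose size-0 loop contains
the nick is *not* a stack (no stacking bonus, and its pairs have no
stacked neighbour for the lonely-pair rule).  The exterior-like scoring of
nick-containing loops is an approximation inherited from the concatenation
approach; its known cost is that extensions of constrained helices are
scored as if exterior.

**Lonely-pair filtering** (`allow_isolated=False`, the demo
configuration) removes all structures containing a helix of fewer than
two stacked pairs, implemented exactly (branch decomposition over
stack-continuation terms), not as a post-hoc filter.

Inside and outside passes give exact pair probabilities; both engines are
checked against exhaustive Boltzmann enumeration to 1e-9 on random
instances, including constraints, nicks and the lonely-pair rule.

## Scoring and decoding

Combined reliabilities follow the expected-accuracy decomposition
(README): a base pair credits its two columns (factor 2), unpaired columns
credit α each.  Only the pair/single-stranded ratio matters to the argmax;
α defaults to 0.2 and β (thermodynamic weight) to 1.0 — configuration
values, not fitted claims.  Gapped cells contribute 0 to a row's pair term
and 1 to its single-stranded term (a gap is vacuously unpaired); this
convention is used identically in Steps 1 and 2.

The decoder is an exact Nussinov-style maximiser over nested structures
with deterministic tie-breaks (prefer unpaired, then smallest left index,
then smallest partner), honouring forced-unpaired/forced-pair constraints
and per-pair weight overrides.

## Step 1 specifics

The adaptive cutoff starts at max(δ, δ_floor, 0.5) — δ is the configured
cutoff (demo default 0.9), and 0.5 is a hard floor because the
conflict-free guarantee of strict-majority selection holds only on the
normalised scale R_bp/(1+β) ∈ [0, 1].  Each failed γ gate raises the
cutoff by δ_step (default 0.05) until the gate passes or the selection is
empty (an empty partial structure has ensemble probability 1 in every
model and always passes).

The γ gate reads "probable in the evolutionary model OR in the
thermodynamic model", with the thermodynamic side aggregated over
sequences by **minimum** (strictest reading of "each sequence must remain
probable"); mean aggregation is available (`gamma_agg="mean"`).

Stem extension processes maximal helices 5′→3′, inner candidates before
outer ones, accepts a candidate only if the extended stem's average
normalised reliability stays above the cutoff *and* the γ gate passes
with the candidate added (re-evaluated after every single pair — the
conservative reading), and never removes pairs.  Consensus pairs whose
projection to a row hits a gap are dropped for that row; non-canonical
projections are dropped with a notice before ensemble probabilities are
computed.

## Step 2 specifics

Both partial structures' positions are forced single-stranded in every
row's cofold and in the constrained phylo-SCFG on the concatenated
alignment (3 prior-free linker columns; display output uses a single `&`
column; part-2 columns are numbered L1+1 … L1+L2 in both modes).

Rescaling: raw constrained probabilities are conditional on the partial
structures, so free pairs (and unpaired probabilities) are multiplied by
both ensemble probabilities — per sequence in the thermodynamic part, the
evolutionary pair in the evolutionary part — while σᵖ pairs are set to
their fixed ensemble probability to keep them out of competition with the
cofold probabilities.  A simplified mode (`eq15`) scores σᵖ pairs as 1
instead.  A row whose σᵖ projection has zero ensemble probability keeps
folding with scale factor 0 and is flagged in the log.

With both partial structures empty the whole Step-2 machinery reduces
exactly (≤ 1e-12) to plain combined scoring of the concatenated
alignment; this reduction is asserted in the tests.

Iterating Step 2 with additional constrained inter-molecular layers is
deliberately not implemented; the weighting of successively conditioned
probabilities is an open problem and out of scope.

## Synthetic benchmark

`SyntheticSpec` defaults define the study conditions: 5 taxa on the tree
`((t1:0.25,t2:0.25):0.15,(t3:0.25,t4:0.25):0.15,t5:0.35)`, two 60-column
parts, two 4-bp stems per part (outer pairs (6,25) and (35,54)), and a
6-bp antiparallel interaction site (part-1 columns 12–17 × part-2 columns
18–13) placed in the first hairpin loops so the true joint structure is a
double kissing hairpin.  Planted pair columns (intra and inter) evolve
jointly under the 16-state model restricted to canonical states — every
row shows a canonical pair, but the pair type covaries; generation
resamples (deterministically from the seed) until at least 2 of the 6
site columns show more than one pair type.  Branch lengths were chosen
moderately deep because compensatory changes, the signal the method
exploits, are vanishingly rare on shallow trees.

The benchmark configuration is δ = 0.55, γ = 0.1, isolated pairs
disallowed, stem extension off.  Two of these deserve justification:

* δ = 0.55, not the demo 0.9: reliability cutoffs do not transfer across
  scoring engines.  On the normalised scale the in-package energy model
  assigns 4-bp stems (the mandated planted elements) thermodynamic mass
  around 0.2–0.3, so combined normalised reliabilities of true pairs sit
  near 0.55–0.65 and a 0.9 cutoff can never select anything; 0.55 sits
  just above the theoretical 0.5 floor.  Training δ and γ on verified
  interaction data is explicitly out of scope.
* extension off: extending constrained stems can close the loop hosting
  an interaction site (inner extensions consume loop columns), a
  documented failure mode of hierarchical constraining; the recovery
  experiment measures site recovery, and extension has its own unit
  tests.

What passing shows: the pipeline turns planted covariation plus
thermodynamic plausibility into the correct pseudoknotted joint
structure on clean, gapless, perfectly aligned families.  What it does
not show: robustness to alignment error, indels, rate heterogeneity,
non-canonical pairs in real helices, or misspecified taxon pairing.

## Numerical and degenerate-input choices

* Probabilities in linear space with per-column scaling (SCFG) and raw
  Boltzmann weights (thermo; magnitudes stay far from overflow at the
  intended alignment scale of a few hundred columns).
* Zero-likelihood columns (possible only with zero-length branches and
  conflicting residues) make the evolutionary part infeasible; this is
  reported as a −inf log-likelihood, not an exception.
* Infeasible constraint sets yield ensemble probability 0 / empty
  posteriors with a flag rather than errors.
* n = 1 alignments are accepted with the evolutionary part disabled.
* All public coordinates are 1-based closed intervals; internal arrays
  are 0-based.

## Problem sizes in the test-suite

Oracle-equivalence checks run at the largest sizes where exhaustive
enumeration stays exact and fast: sequences ≤ 14 nt (thermodynamics),
alignments ≤ 8 columns × 3 rows (parse trees), matrices ≤ 14 columns
(decoder).  The end-to-end benchmark uses 20 replicates of the 60+60
study conditions.
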