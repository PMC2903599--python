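# Default parameter set for the evolutionary model.
#
# The grammar production probabilities are the widely reproduced values of
# the Pfold lightweight structure grammar (S -> LS | L, L -> s | dFd,
# F -> dFd | LS), estimated originally from rRNA/tRNA alignments.
#
# The substitution-rate parameters below are SYNTHETIC: a reversible
# HKY-style 4-state model for unpaired columns and a reversible 16-state
# dinucleotide model whose stationary distribution concentrates on the six
# canonical pairs, with single-nucleotide changes at unit exchangeability
# and compensatory double substitutions between canonical pairs at reduced
# exchangeability.  They are constructed in-package (see jointfold.params),
# not taken from any published fit.
grammar:
  S_LS: 0.868534
  S_L: 0.131466
  L_s: 0.894603
  L_dFd: 0.105397
  F_dFd: 0.787640
  F_LS: 0.212360
single_model:
  frequencies: {A: 0.27, C: 0.22, G: 0.26, U: 0.25}
  kappa: 4.0
pair_model:
  canonical_frequencies: {AU: 0.177, UA: 0.177, GC: 0.234, CG: 0.234, GU: 0.049, UG: 0.049}
  noncanonical_frequency_total: 0.08
  single_change_exchangeability: 1.0
  double_canonical_exchangeability: 0.25
  double_other_exchangeability: 0.0
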