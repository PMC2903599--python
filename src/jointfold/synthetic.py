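"""Synthetic alignment pairs with planted structure and a covarying
inter-molecular binding site.

The generator emulates the evolutionary signal the method exploits: a
root sequence pair is evolved down a phylogenetic tree; unpaired columns
evolve under the 4-state model, while planted intra-molecular helices and
the planted interaction site evolve jointly as dinucleotide pair states
under the 16-state model restricted to canonical pairs (compensatory
co-substitution: every row keeps a canonical pair, but the pair type
covaries along the tree).

What it does not emulate: alignment errors, indel histories (gaps are
optional uniform noise, not evolved), rate variation across sites and
non-canonical wobble in planted elements — passing end-to-end tests on
these fixtures shows the machinery recovers planted covariation, not that
real alignments are this clean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .assemble import (
    LAYER_CONSTRAINED,
    LAYER_INTER,
    JointStructure,
)
from .msa_io import AlignmentPair, MultipleAlignment
from .params import ParameterSet, default_parameter_set
from .phylo import CANONICAL_PAIRS, PAIR_STATES, RESIDUES, PhyloTree

log = logging.getLogger(__name__)

#: moderately diverged five-taxon family; enough divergence that planted
#: pair columns actually show compensatory changes rather than mere
#: conservation
DEFAULT_NEWICK = "((t1:0.25,t2:0.25):0.15,(t3:0.25,t4:0.25):0.15,t5:0.35);"


@dataclass
class SyntheticSpec:
    """Study conditions for a synthetic alignment pair.

    Stems are (outer_i, outer_j, n_pairs) in part-local 1-based columns;
    the interaction site pairs part-1 columns site1..site1+len-1 with
    part-2 columns site2+len-1..site2 (antiparallel).
    """

    newick: str = DEFAULT_NEWICK
    len1: int = 60
    len2: int = 60
    stems1: tuple = ((6, 25, 4), (35, 54, 4))
    stems2: tuple = ((6, 25, 4), (35, 54, 4))
    site1: int = 12
    site2: int = 13
    site_len: int = 6
    min_compensatory: int = 2
    gap_prob: float = 0.0
    seed: int = 0

    def stem_pairs(self, part: int):
        stems = self.stems1 if part == 1 else self.stems2
        out = []
        for i, j, k in stems:
            out.extend((i + d, j - d) for d in range(k))
        return out

    def inter_pairs(self):
        return [
            (self.site1 + d, self.site2 + self.site_len - 1 - d)
            for d in range(self.site_len)
        ]

    def validate(self):
        for part, L in ((1, self.len1), (2, self.len2)):
            pairs = self.stem_pairs(part)
            used = set()
            for i, j in pairs:
                if not (1 <= i < j <= L):
                    raise ValueError(f"stem pair ({i}, {j}) outside part {part}")
                if i in used or j in used:
                    raise ValueError(f"overlapping planted stems in part {part}")
                used.update((i, j))
            site = (
                range(self.site1, self.site1 + self.site_len)
                if part == 1
                else range(self.site2, self.site2 + self.site_len)
            )
            for p in site:
                if p in used or not 1 <= p <= L:
                    raise ValueError(
                        f"interaction site overlaps a stem in part {part}"
                    )


def _canonical_transition(P16: np.ndarray) -> np.ndarray:
    """Transition matrix restricted and renormalised to canonical states."""
    idx = [PAIR_STATES.index(p) for p in CANONICAL_PAIRS]
    sub = P16[np.ix_(idx, idx)]
    return sub / sub.sum(axis=1, keepdims=True)


def generate_pair(
    spec: SyntheticSpec, models: ParameterSet | None = None
) -> tuple[AlignmentPair, JointStructure, PhyloTree]:
    """Generate an alignment pair, its ground truth, and the generating tree.

    Deterministic given ``spec.seed``.  Resamples (bounded) until at least
    ``min_compensatory`` of the interaction-site column pairs show more
    than one canonical pair type across the rows.
    """
    spec.validate()
    models = models or default_parameter_set()
    rng = np.random.default_rng(spec.seed)
    tree = PhyloTree.from_newick(spec.newick)
    taxa = tree.taxa
    pairs1 = spec.stem_pairs(1)
    pairs2 = spec.stem_pairs(2)
    inter = spec.inter_pairs()

    cidx = [PAIR_STATES.index(p) for p in CANONICAL_PAIRS]
    pi_c = models.pair_model.pi[cidx]
    pi_c = pi_c / pi_c.sum()

    # joint column model: treat every planted pair (intra both parts plus
    # inter-molecular) as one 6-state canonical site
    paircols = (
        [(i, j, 1) for i, j in pairs1]
        + [(i, j, 2) for i, j in pairs2]
        + [(i, j, 12) for i, j in inter]
    )
    paired_pos = {1: set(), 2: set()}
    for i, j, tag in paircols:
        if tag == 1:
            paired_pos[1].update((i, j))
        elif tag == 2:
            paired_pos[2].update((i, j))
        else:
            paired_pos[1].add(i)
            paired_pos[2].add(j)
    single1 = [c for c in range(1, spec.len1 + 1) if c not in paired_pos[1]]
    single2 = [c for c in range(1, spec.len2 + 1) if c not in paired_pos[2]]

    for attempt in range(200):
        # evolve states down the tree
        root_single = rng.choice(4, size=len(single1) + len(single2),
                                 p=models.single_model.pi)
        root_pairs = rng.choice(6, size=len(paircols), p=pi_c)
        states = {tree.root: (root_single, root_pairs)}
        order = [tree.root]
        stack = [tree.root]
        while stack:
            node = stack.pop()
            for ch in tree.children[node]:
                t = float(tree.blen[ch])
                P4 = models.single_model.transition(t)
                P6 = _canonical_transition(models.pair_model.transition(t))
                ps, pp = states[node]
                new_s = np.array(
                    [rng.choice(4, p=P4[x]) for x in ps], dtype=int
                )
                new_p = np.array(
                    [rng.choice(6, p=P6[x]) for x in pp], dtype=int
                )
                states[ch] = (new_s, new_p)
                stack.append(ch)
        # assemble leaf rows
        rows1, rows2 = [], []
        for leaf in range(len(taxa)):
            s_states, p_states = states[leaf]
            r1 = [""] * spec.len1
            r2 = [""] * spec.len2
            for pos, x in zip(single1, s_states[: len(single1)]):
                r1[pos - 1] = RESIDUES[x]
            for pos, x in zip(single2, s_states[len(single1):]):
                r2[pos - 1] = RESIDUES[x]
            for (i, j, tag), x in zip(paircols, p_states):
                a, b = CANONICAL_PAIRS[x]
                if tag == 1:
                    r1[i - 1], r1[j - 1] = a, b
                elif tag == 2:
                    r2[i - 1], r2[j - 1] = a, b
                else:
                    r1[i - 1], r2[j - 1] = a, b
            rows1.append("".join(r1))
            rows2.append("".join(r2))
        # compensatory-change requirement on the interaction site
        offset = len(pairs1) + len(pairs2)
        site_states = np.array(
            [states[leaf][1][offset:] for leaf in range(len(taxa))]
        )
        n_varying = sum(
            len(set(site_states[:, k])) > 1 for k in range(len(inter))
        )
        if n_varying >= spec.min_compensatory:
            break
    else:
        raise RuntimeError(
            "could not generate the requested compensatory variation"
        )
    if spec.gap_prob > 0:
        rows1 = [_inject_gaps(r, spec.gap_prob, rng, paired_pos[1]) for r in rows1]
        rows2 = [_inject_gaps(r, spec.gap_prob, rng, paired_pos[2]) for r in rows2]
    aln1 = MultipleAlignment(list(taxa), rows1)
    aln2 = MultipleAlignment(list(taxa), rows2)
    pair = AlignmentPair(
        aln1, aln2, [(t, t) for t in taxa],
        list(range(1, spec.len1 + 1)), list(range(1, spec.len2 + 1)),
    )
    layers = {}
    reliab = {}
    for i, j in pairs1:
        layers[(i, j)] = LAYER_CONSTRAINED
    for i, j in pairs2:
        layers[(i + spec.len1, j + spec.len1)] = LAYER_CONSTRAINED
    inter_global = frozenset((i, j + spec.len1) for i, j in inter)
    for p in inter_global:
        layers[p] = LAYER_INTER
    truth = JointStructure(
        spec.len1, spec.len2,
        frozenset(pairs1), frozenset(pairs2), inter_global, layers, reliab,
    )
    log.info("synthetic pair generated (attempt %d, %d covarying site columns)",
             attempt + 1, n_varying)
    return pair, truth, tree


def _inject_gaps(row: str, p: float, rng, protected: set) -> str:
    out = list(row)
    for c in range(len(out)):
        if (c + 1) not in protected and rng.random() < p:
            out[c] = "-"
    return "".join(out)
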