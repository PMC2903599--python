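"""Final decoding and output rendering of the joint structure.

The maximum-expected-accuracy decoder runs on the Step-2 reliabilities
with the partial-structure positions excluded (weight 0), which lets the
new layer cross the constrained layer; the partial-structure pairs are
then re-added unconditionally.  Pairs are classified into three layers
with distinct bracket classes:

    [ ]  constrained pairs from Step 1 (the partial structures)
    ( )  new intra-molecular pairs from Step 2
    < >  inter-molecular pairs (the predicted interaction)

Pairs within a layer are nested; crossings (pseudoknots, e.g. kissing
hairpins) occur only between the constrained layer and the Step-2 layers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evoscfg import StructureConstraint, pairs_cross
from .msa_io import AlignmentPair, LINKER_DISPLAY
from .params import Params
from .scoring import ReliabilityMatrix, mea_decode
from .step1 import PartialStructure
from .step2 import Step2Reliabilities, global_partial_pairs

log = logging.getLogger(__name__)

LAYER_CONSTRAINED = "constrained"
LAYER_INTRA = "step2-intra"
LAYER_INTER = "step2-inter"

_BRACKETS = {
    LAYER_CONSTRAINED: "[]",
    LAYER_INTRA: "()",
    LAYER_INTER: "<>",
}


class AssemblyError(RuntimeError):
    """Internal inconsistency in the assembled joint structure."""


@dataclass
class JointStructure:
    """Partition of the predicted base pairs into the three layers.

    ``sigma1``/``sigma2`` hold intra-molecular pairs in part-local 1-based
    coordinates, ``sigma_int`` inter-molecular pairs in global logical
    coordinates (i <= L1 < j).  ``layers`` maps every pair (in global
    logical coordinates) to its layer tag and ``reliability`` to its
    reported score.
    """

    L1: int
    L2: int
    sigma1: frozenset
    sigma2: frozenset
    sigma_int: frozenset
    layers: dict
    reliability: dict

    def __post_init__(self):
        self.validate()

    def global_pairs(self) -> dict:
        out = {}
        for i, j in self.sigma1:
            out[(i, j)] = self.layers[(i, j)]
        for i, j in self.sigma2:
            out[(i + self.L1, j + self.L1)] = self.layers[(i + self.L1, j + self.L1)]
        for i, j in self.sigma_int:
            out[(i, j)] = self.layers[(i, j)]
        return out

    def validate(self):
        allp = self.global_pairs()
        seen: set[int] = set()
        for i, j in allp:
            if not (1 <= i < j <= self.L1 + self.L2):
                raise AssemblyError(f"pair ({i}, {j}) out of range")
            if i in seen or j in seen:
                raise AssemblyError(f"position reused at pair ({i}, {j})")
            seen.update((i, j))
        for i, j in self.sigma_int:
            if not (i <= self.L1 < j):
                raise AssemblyError(f"inter pair ({i}, {j}) does not cross parts")
        for i, j in self.sigma1 | self.sigma2:
            pass
        by_layer: dict = {}
        for p, layer in allp.items():
            by_layer.setdefault(layer, []).append(p)
        for layer, plist in by_layer.items():
            plist = sorted(plist)
            for a in range(len(plist)):
                for b in range(a + 1, len(plist)):
                    if pairs_cross(plist[a], plist[b]):
                        raise AssemblyError(
                            f"pairs {plist[a]} and {plist[b]} cross within "
                            f"layer {layer}"
                        )
        # step2 layers are one nested decode; they may cross only the
        # constrained layer
        step2 = sorted(
            p for p, l in allp.items() if l in (LAYER_INTRA, LAYER_INTER)
        )
        for a in range(len(step2)):
            for b in range(a + 1, len(step2)):
                if pairs_cross(step2[a], step2[b]):
                    raise AssemblyError(
                        f"step-2 pairs {step2[a]} and {step2[b]} cross"
                    )

    @property
    def interaction_reliability(self) -> float:
        """Summed reliability of inter-molecular pairs (convenience metric,
        not part of the published scoring)."""
        return float(sum(self.reliability.get(p, 0.0) for p in self.sigma_int))


def final_decode(
    rel2: Step2Reliabilities,
    partials: tuple[PartialStructure, PartialStructure],
    params: Params,
) -> JointStructure:
    """Decode Step-2 reliabilities and re-add the partial structures."""
    p1, p2 = partials
    L1 = rel2.L1
    Lc = rel2.ss.shape[0]
    L2 = Lc - L1
    fixed = global_partial_pairs(p1, p2, L1)
    forced_unpaired = frozenset(p for ij in fixed for p in ij)
    decoded = mea_decode(
        ReliabilityMatrix(rel2.pair, rel2.ss, rel2.beta, rel2.alpha, "step2"),
        StructureConstraint(forced_unpaired=forced_unpaired),
    )
    sigma1, sigma2, sigma_int = set(), set(), set()
    layers, reliab = {}, {}
    for i, j in decoded:
        if j <= L1:
            sigma1.add((i, j))
            layers[(i, j)] = LAYER_INTRA
        elif i > L1:
            sigma2.add((i - L1, j - L1))
            layers[(i, j)] = LAYER_INTRA
        else:
            sigma_int.add((i, j))
            layers[(i, j)] = LAYER_INTER
        reliab[(i, j)] = float(rel2.pair[i - 1, j - 1])
    n = len(p1.th_probs)
    for (i, j), part in fixed.items():
        if (i, j) in layers:
            raise AssemblyError(f"constrained pair ({i}, {j}) also decoded")
        layers[(i, j)] = LAYER_CONSTRAINED
        src = p1 if part == 1 else p2
        reliab[(i, j)] = float(
            src.ev_prob + (rel2.beta / n) * sum(src.th_probs)
        )
        if part == 1:
            sigma1.add((i, j))
        else:
            sigma2.add((i - L1, j - L1))
    return JointStructure(
        L1, L2, frozenset(sigma1), frozenset(sigma2), frozenset(sigma_int),
        layers, reliab,
    )


def structure_string(joint: JointStructure) -> str:
    """Bracket annotation over the display concatenation (with '&')."""
    L1, L2 = joint.L1, joint.L2
    chars = ["."] * (L1 + 1 + L2)
    chars[L1] = LINKER_DISPLAY

    def disp(c):
        return c - 1 if c <= L1 else c

    for (i, j), layer in joint.global_pairs().items():
        o, cch = _BRACKETS[layer]
        chars[disp(i)] = o
        chars[disp(j)] = cch
    return "".join(chars)


def parse_structure_string(s: str) -> dict:
    """Inverse of :func:`structure_string`: global pairs by layer.

    Returns {(i, j): layer} in logical coordinates; the '&' column is
    skipped.  Raises on unbalanced brackets per layer.
    """
    stacks = {layer: [] for layer in _BRACKETS}
    openers = {v[0]: k for k, v in _BRACKETS.items()}
    closers = {v[1]: k for k, v in _BRACKETS.items()}
    out = {}
    col = 0
    for ch in s:
        if ch == LINKER_DISPLAY:
            continue
        col += 1
        if ch in openers:
            stacks[openers[ch]].append(col)
        elif ch in closers:
            layer = closers[ch]
            if not stacks[layer]:
                raise ValueError(f"unbalanced {ch!r} at column {col}")
            out[(stacks[layer].pop(), col)] = layer
    for layer, st in stacks.items():
        if st:
            raise ValueError(f"unclosed {_BRACKETS[layer][0]!r} in layer {layer}")
    return out


def render(
    joint: JointStructure,
    pair_aln: AlignmentPair,
    gap_filter: float | None = None,
) -> str:
    """Stockholm-style text report of the joint structure.

    ``gap_filter`` hides display columns whose gap fraction is >= the
    threshold (rendering only; pairs with a hidden end are dropped from
    the annotation line but stay in the pair table).
    """
    aln1, aln2 = pair_aln.aln1, pair_aln.aln2
    L1, L2 = aln1.length, aln2.length
    rows = [r1 + LINKER_DISPLAY + r2 for r1, r2 in zip(aln1.rows, aln2.rows)]
    names = [
        a if a == b else f"{a}&{b}" for a, b in pair_aln.taxon_map
    ]
    ss = structure_string(joint)
    visible = list(range(L1 + 1 + L2))
    if gap_filter is not None:
        n = len(rows)
        visible = [
            c
            for c in range(L1 + 1 + L2)
            if c == L1
            or sum(r[c] == "-" for r in rows) / n < gap_filter
        ]
        hidden = set(range(L1 + 1 + L2)) - set(visible)
        ss_list = list(ss)
        pairs_disp = {}
        for (i, j), layer in joint.global_pairs().items():
            di = i - 1 if i <= L1 else i
            dj = j - 1 if j <= L1 else j
            if di in hidden or dj in hidden:
                for d in (di, dj):
                    if d not in hidden:
                        ss_list[d] = "."
        ss = "".join(ss_list)
        rows = ["".join(r[c] for c in visible) for r in rows]
        ss = "".join(ss[c] for c in visible)
    width = max(len(x) for x in names + ["#=GC SS_joint"]) + 2
    lines = ["# STOCKHOLM 1.0", "#=GF CC joint secondary structure prediction"]
    for name, row in zip(names, rows):
        lines.append(f"{name:<{width}}{row}")
    lines.append(f"{'#=GC SS_joint':<{width}}{ss}")
    lines.append("#=GF CC pair table: part i j layer reliability")
    for (i, j), layer in sorted(joint.global_pairs().items()):
        if j <= joint.L1:
            part, pi, pj = 1, i, j
        elif i > joint.L1:
            part, pi, pj = 2, i - joint.L1, j - joint.L1
        else:
            part, pi, pj = "int", i, j - joint.L1
        lines.append(
            f"#=GF PAIR {part} {pi} {pj} {layer} "
            f"{joint.reliability.get((i, j), 0.0):.4f}"
        )
    lines.append("//")
    return "\n".join(lines) + "\n"
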