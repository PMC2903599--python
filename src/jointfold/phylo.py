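"""Phylogenetic machinery for the evolutionary model.

Provides the tree (neighbour joining on Jukes-Cantor distances, or a
user-supplied Newick), reversible substitution models over single columns
(4 states) and base-paired column pairs (16 dinucleotide states), and the
Felsenstein pruning likelihoods that serve as emission terms of the
phylo-SCFG.

Gaps are treated as missing data (all-ones partial likelihood).  For a
paired emission, a leaf gapped in exactly one of the two columns is treated
as missing in both (configurable via ``pair_gap_policy``); IUPAC ambiguity
codes are marginalised over their compatible residues.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio import Phylo
from Bio.Phylo.TreeConstruction import DistanceMatrix, DistanceTreeConstructor

from .msa_io import IUPAC_CODES, MultipleAlignment

RESIDUES = "ACGU"
_RIDX = {r: i for i, r in enumerate(RESIDUES)}
PAIR_STATES = [a + b for a in RESIDUES for b in RESIDUES]
CANONICAL_PAIRS = ("AU", "UA", "GC", "CG", "GU", "UG")


class TreeError(ValueError):
    pass


class DistanceError(TreeError):
    pass


def residue_indicator(ch: str) -> np.ndarray:
    """Partial-likelihood vector of a residue/gap at a leaf (4 states)."""
    v = np.zeros(4)
    if ch == "-":
        return np.ones(4)
    for r in IUPAC_CODES[ch]:
        v[_RIDX[r]] = 1.0
    return v


# ---------------------------------------------------------------------------
# tree


@dataclass
class PhyloTree:
    """Rooted tree stored as flat arrays in postorder.

    ``children[i]`` lists the child node indices of node ``i`` and
    ``blen[i]`` is the branch length (expected substitutions/site) of the
    edge above node ``i``.  Leaves are the first ``len(taxa)`` node indices,
    ordered as ``taxa``.
    """

    taxa: list[str]
    children: list[list[int]]
    blen: np.ndarray
    root: int

    def __post_init__(self):
        self.blen = np.asarray(self.blen, dtype=float)
        if np.any(self.blen < 0) or not np.all(np.isfinite(self.blen)):
            raise TreeError("branch lengths must be finite and >= 0")
        order: list[int] = []

        def walk(i):
            for c in self.children[i]:
                walk(c)
            order.append(i)

        walk(self.root)
        self.postorder = order

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @classmethod
    def from_newick(cls, text: str, taxa_order: list[str] | None = None) -> "PhyloTree":
        tree = Phylo.read(io.StringIO(text), "newick")
        return cls.from_biopython(tree, taxa_order)

    @classmethod
    def from_biopython(cls, tree, taxa_order: list[str] | None = None) -> "PhyloTree":
        leaves = [t.name for t in tree.get_terminals()]
        if taxa_order is None:
            taxa_order = leaves
        if set(leaves) != set(taxa_order):
            raise TreeError(
                f"tree leaves {sorted(leaves)} do not match taxa {sorted(taxa_order)}"
            )
        children: list[list[int]] = [[] for _ in taxa_order]
        blen = [0.0] * len(taxa_order)
        leaf_idx = {t: i for i, t in enumerate(taxa_order)}

        def build(clade) -> int:
            if clade.is_terminal():
                i = leaf_idx[clade.name]
            else:
                kids = [build(c) for c in clade.clades]
                i = len(children)
                children.append(kids)
                blen.append(0.0)
            b = clade.branch_length
            blen[i] = max(0.0, float(b) if b is not None else 0.0)
            return i

        root = build(tree.root)
        return cls(list(taxa_order), children, np.array(blen), root)

    def to_newick(self) -> str:
        def fmt(i):
            if not self.children[i]:
                return f"{self.taxa[i]}:{self.blen[i]:.6f}"
            inner = ",".join(fmt(c) for c in self.children[i])
            return f"({inner}):{self.blen[i]:.6f}"

        return fmt(self.root) + ";"


def jc_distance(row_a: str, row_b: str) -> float:
    """Jukes-Cantor distance between two gapped rows (gaps excluded pairwise)."""
    shared = mism = 0
    for a, b in zip(row_a, row_b):
        if a == "-" or b == "-":
            continue
        shared += 1
        if a != b:
            mism += 1
    if shared == 0:
        raise DistanceError("no shared non-gap columns")
    p = mism / shared
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        raise DistanceError(f"saturated JC distance (p = {p:.3f})")
    return max(0.0, -0.75 * float(np.log(arg)))


def estimate_tree(aln: MultipleAlignment) -> PhyloTree:
    """Neighbour-joining tree from pairwise Jukes-Cantor distances.

    Negative NJ branch lengths are clamped to 0.  Deterministic given the
    input row order.  A concatenated alignment should be passed through
    :meth:`ConcatenatedAlignment.to_alignment` first (linker columns as
    ``N`` carry no signal).
    """
    n = aln.n_seqs
    if n < 2:
        raise TreeError("tree estimation requires at least 2 sequences")
    dist = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        try:
            d = jc_distance(aln.rows[i], aln.rows[j])
        except DistanceError as exc:
            raise DistanceError(
                f"distance undefined between {aln.taxon_ids[i]!r} and "
                f"{aln.taxon_ids[j]!r}: {exc}"
            ) from exc
        dist[i, j] = dist[j, i] = d
    if n == 2:
        d = dist[0, 1]
        return PhyloTree(
            list(aln.taxon_ids), [[], [], [0, 1]], np.array([d / 2, d / 2, 0.0]), 2
        )
    # Biopython's DistanceMatrix wants a lower-triangular list of lists
    matrix = [[float(dist[i, j]) for j in range(i)] + [0.0] for i in range(n)]
    dm = DistanceMatrix(names=list(aln.taxon_ids), matrix=matrix)
    bptree = DistanceTreeConstructor().nj(dm)
    for clade in bptree.find_clades():
        if clade.branch_length is not None and clade.branch_length < 0:
            clade.branch_length = 0.0
    return PhyloTree.from_biopython(bptree, list(aln.taxon_ids))


def read_tree(path, taxa_order: list[str] | None = None) -> PhyloTree:
    with open(path) as fh:
        return PhyloTree.from_newick(fh.read(), taxa_order)


# ---------------------------------------------------------------------------
# substitution models


def _validate_rate_matrix(Q: np.ndarray, pi: np.ndarray, k: int, reversible: bool):
    if Q.shape != (k, k) or pi.shape != (k,):
        raise ValueError("model dimension mismatch")
    if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-9):
        raise ValueError("rate matrix rows must sum to 0")
    if abs(pi.sum() - 1.0) > 1e-9 or np.any(pi < 0):
        raise ValueError("stationary distribution must be a probability vector")
    if reversible:
        flux = pi[:, None] * Q
        if not np.allclose(flux, flux.T, atol=1e-8):
            raise ValueError("model declared reversible but detailed balance fails")


@dataclass
class SingleSubstModel:
    """Reversible 4-state substitution model for unpaired columns."""

    pi: np.ndarray
    Q: np.ndarray
    reversible: bool = True

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        _validate_rate_matrix(self.Q, self.pi, 4, self.reversible)
        self._pcache: dict[float, np.ndarray] = {}

    def transition(self, t: float) -> np.ndarray:
        if t not in self._pcache:
            self._pcache[t] = expm_rate(self.Q, t)
        return self._pcache[t]


@dataclass
class PairSubstModel:
    """Reversible 16-state model over dinucleotide pair states.

    When ``canonical_concentrated`` is declared, at least 80% of the
    stationary mass must sit on the six canonical pairs; this is asserted
    against loaded parameters.
    """

    pi: np.ndarray
    Q: np.ndarray
    reversible: bool = True
    canonical_concentrated: bool = True

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        _validate_rate_matrix(self.Q, self.pi, 16, self.reversible)
        if self.canonical_concentrated:
            mass = sum(self.pi[PAIR_STATES.index(p)] for p in CANONICAL_PAIRS)
            if mass < 0.8:
                raise ValueError(
                    f"canonical pair stationary mass {mass:.3f} < 0.8 "
                    "but model is declared canonical-concentrated"
                )
        self._pcache: dict[float, np.ndarray] = {}

    def transition(self, t: float) -> np.ndarray:
        if t not in self._pcache:
            self._pcache[t] = expm_rate(self.Q, t)
        return self._pcache[t]


def expm_rate(Q: np.ndarray, t: float, tol: float = 1e-12) -> np.ndarray:
    """exp(Q t) by eigendecomposition, with a scaling-and-squaring fallback.

    The eigendecomposition is accepted only if it reconstructs Q within
    ``tol`` (relative to the largest rate); otherwise scipy's Pade
    scaling-and-squaring implementation is used.
    """
    Q = np.asarray(Q, dtype=float)
    if t == 0.0:
        return np.eye(Q.shape[0])
    try:
        w, V = np.linalg.eig(Q)
        Vi = np.linalg.inv(V)
        recon = (V * w) @ Vi
        scale = max(1.0, float(np.abs(Q).max()))
        if np.abs(recon - Q).max() <= tol * scale:
            P = (V * np.exp(w * t)) @ Vi
            P = np.real_if_close(P, tol=1e6)
            P = np.real(P)
            np.clip(P, 0.0, None, out=P)
            # renormalise tiny negative round-off
            P /= P.sum(axis=1, keepdims=True)
            return P
    except np.linalg.LinAlgError:
        pass
    from scipy.linalg import expm

    P = expm(Q * t)
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def reversible_rate_matrix(pi: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Build a reversible rate matrix from exchangeabilities ``S`` and ``pi``.

    Off-diagonals Q_xy = S_xy * pi_y; rows are filled to sum to zero and the
    matrix is scaled to one expected substitution per unit time.
    """
    pi = np.asarray(pi, float)
    Q = np.asarray(S, float) * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -float(np.dot(pi, np.diag(Q)))
    if rate <= 0:
        raise ValueError("degenerate rate matrix")
    return Q / rate


# ---------------------------------------------------------------------------
# pruning likelihoods


def _leaf_indicators_single(aln: MultipleAlignment) -> np.ndarray:
    """(n_seqs, L, 4) partial-likelihood indicators for every cell."""
    out = np.empty((aln.n_seqs, aln.length, 4))
    for k, row in enumerate(aln.rows):
        for c, ch in enumerate(row):
            out[k, c] = residue_indicator(ch)
    return out


def column_logliks(
    tree: PhyloTree, model: SingleSubstModel, aln: MultipleAlignment
) -> np.ndarray:
    """Log-likelihood of every alignment column under the unpaired model.

    Vectorised Felsenstein pruning over all columns at once; returns an
    array of length L.  Columns with zero likelihood (possible only with
    zero-length branches) come back as ``-inf``.
    """
    ind = _leaf_indicators_single(aln)  # (n, L, 4)
    n_leaves = len(tree.taxa)
    if aln.n_seqs != n_leaves:
        raise ValueError("column count of leaves does not match tree")
    partial = {}
    for node in tree.postorder:
        if not tree.children[node]:
            partial[node] = ind[node]
        else:
            acc = np.ones_like(ind[0])
            for c in tree.children[node]:
                P = model.transition(float(tree.blen[c]))
                acc = acc * (partial.pop(c) @ P.T)
            partial[node] = acc
    lik = partial[tree.root] @ model.pi
    with np.errstate(divide="ignore"):
        return np.log(lik)


def column_loglik(tree, model, column) -> float:
    """Log-likelihood of a single column given as a list of residues/gaps."""
    aln = MultipleAlignment(list(tree.taxa), [str(c) for c in column])
    return float(column_logliks(tree, model, aln)[0])


def paircol_logliks(
    tree: PhyloTree,
    model: PairSubstModel,
    aln: MultipleAlignment,
    pairs: np.ndarray,
    pair_gap_policy: str = "missing_both",
) -> np.ndarray:
    """Log-likelihoods of base-paired column pairs under the 16-state model.

    ``pairs`` is an (m, 2) array of 0-based column indices.  Pruning is
    vectorised over all requested pairs.  Under the default policy a leaf
    gapped in exactly one of the two columns is treated as missing in both;
    ``marginalise`` instead keeps the observed residue and marginalises the
    gapped side.
    """
    pairs = np.asarray(pairs, dtype=int)
    if pairs.size == 0:
        return np.zeros(0)
    ind4 = _leaf_indicators_single(aln)  # (n, L, 4)
    m = len(pairs)
    leaf_ind = np.empty((aln.n_seqs, m, 16))
    for k, row in enumerate(aln.rows):
        a = ind4[k, pairs[:, 0]]  # (m, 4)
        b = ind4[k, pairs[:, 1]]
        outer = (a[:, :, None] * b[:, None, :]).reshape(m, 16)
        if pair_gap_policy == "missing_both":
            gap_a = np.array([row[c] == "-" for c in pairs[:, 0]])
            gap_b = np.array([row[c] == "-" for c in pairs[:, 1]])
            outer[gap_a ^ gap_b] = 1.0
        leaf_ind[k] = outer
    partial = {}
    for node in tree.postorder:
        if not tree.children[node]:
            partial[node] = leaf_ind[node]
        else:
            acc = np.ones((m, 16))
            for c in tree.children[node]:
                P = model.transition(float(tree.blen[c]))
                acc = acc * (partial.pop(c) @ P.T)
            partial[node] = acc
    lik = partial[tree.root] @ model.pi
    with np.errstate(divide="ignore"):
        return np.log(lik)


def paircol_loglik(tree, model, col_i, col_j, pair_gap_policy="missing_both") -> float:
    """Log-likelihood of one base-paired column pair (columns as residue lists)."""
    rows = [str(a) + str(b) for a, b in zip(col_i, col_j)]
    aln = MultipleAlignment(list(tree.taxa), rows)
    return float(
        paircol_logliks(tree, model, aln, np.array([[0, 1]]), pair_gap_policy)[0]
    )
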