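"""Reading, validation, pairing and concatenation of the two input alignments.

The pipeline consumes two multiple sequence alignments of homologous RNAs
(one ncRNA family, one putative target region) whose rows correspond to the
same organisms.  This module provides the alignment container, taxon pairing
between the two families, the linker-aware concatenation used in the
cofolding stage, and the column <-> sequence-position coordinate maps.

All public coordinates are 1-based and intervals are closed; internal numpy
arrays are 0-based.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

#: residues accepted on read (after T->U normalisation); '.' is normalised to '-'
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "U": "U", "N": "ACGU",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG",
}
GAP_CHARS = "-."


class AlignmentError(ValueError):
    """Base class for malformed alignment input."""


class RaggedAlignmentError(AlignmentError):
    pass


class EmptyInputError(AlignmentError):
    pass


class AlphabetError(AlignmentError):
    pass


class PairingError(AlignmentError):
    pass


class _Gap:
    """Sentinel returned by coordinate maps for gapped cells."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):  # pragma: no cover - cosmetic
        return "GAP"

    def __bool__(self):
        return False


GAP = _Gap()


def _normalise_row(row: str, taxon: str) -> str:
    out = []
    for col, ch in enumerate(row.upper().replace("T", "U"), start=1):
        if ch in GAP_CHARS:
            out.append("-")
        elif ch in IUPAC_CODES:
            out.append(ch)
        else:
            raise AlphabetError(
                f"unknown residue {ch!r} in row {taxon!r} at column {col}"
            )
    return "".join(out)


@dataclass
class MultipleAlignment:
    """A gapped alignment of homologous RNA sequences over matched columns."""

    taxon_ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if not self.rows:
            raise EmptyInputError("alignment contains no sequences")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise RaggedAlignmentError(
                f"rows have differing lengths: {sorted(lengths)}"
            )
        if len(self.taxon_ids) != len(self.rows):
            raise AlignmentError("taxon_ids and rows differ in count")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise AlignmentError("duplicate taxon ids")
        if self.length < 1:
            raise EmptyInputError("alignment has zero columns")
        self.rows = [
            _normalise_row(r, t) for r, t in zip(self.rows, self.taxon_ids)
        ]
        # per-row maps between 1-based columns and 1-based ungapped positions
        self._col2pos: list[list[int]] = []
        self._pos2col: list[list[int]] = []
        for row in self.rows:
            c2p, p2c, pos = [], [], 0
            for col, ch in enumerate(row, start=1):
                if ch == "-":
                    c2p.append(0)
                else:
                    pos += 1
                    c2p.append(pos)
                    p2c.append(col)
            self._col2pos.append(c2p)
            self._pos2col.append(p2c)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    def ungapped(self, seq_index: int) -> str:
        """Ungapped sequence of row ``seq_index`` (0-based row index)."""
        return self.rows[seq_index].replace("-", "")

    def col_to_seqpos(self, seq_index: int, col: int):
        """1-based ungapped position of column ``col`` in row, or ``GAP``."""
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} outside 1..{self.length}")
        p = self._col2pos[seq_index][col - 1]
        return p if p else GAP

    def seqpos_to_col(self, seq_index: int, pos: int) -> int:
        """Alignment column (1-based) of ungapped position ``pos``."""
        p2c = self._pos2col[seq_index]
        if not 1 <= pos <= len(p2c):
            raise IndexError(f"position {pos} outside 1..{len(p2c)}")
        return p2c[pos - 1]

    def restrict(self, taxa: Sequence[str]) -> tuple["MultipleAlignment", list[int]]:
        """Restrict to ``taxa`` (in that order), dropping all-gap columns.

        Returns the restricted alignment and the list of kept original
        columns (1-based).
        """
        idx = {t: i for i, t in enumerate(self.taxon_ids)}
        rows = [self.rows[idx[t]] for t in taxa]
        kept = [
            c
            for c in range(self.length)
            if any(r[c] != "-" for r in rows)
        ]
        dropped = self.length - len(kept)
        if dropped:
            log.info("dropped %d all-gap columns after taxon restriction", dropped)
        if not kept:
            raise EmptyInputError("all columns are gaps after restriction")
        new_rows = ["".join(r[c] for c in kept) for r in rows]
        return MultipleAlignment(list(taxa), new_rows), [c + 1 for c in kept]


def col_to_seqpos(aln: MultipleAlignment, seq_index: int, col: int):
    return aln.col_to_seqpos(seq_index, col)


_FORMATS = {"fasta": "fasta", "clustal": "clustal", "stockholm": "stockholm"}


def _sniff_format(text: str) -> str:
    for line in text.splitlines():
        if not line.strip():
            continue
        if line.startswith("# STOCKHOLM"):
            return "stockholm"
        if line.upper().startswith("CLUSTAL"):
            return "clustal"
        if line.startswith(">"):
            return "fasta"
        break
    raise AlignmentError("could not auto-detect alignment format")


def read_alignment(path, fmt: str = "auto") -> MultipleAlignment:
    """Read a FASTA/Clustal/Stockholm alignment into a :class:`MultipleAlignment`.

    Rows are uppercased, ``T`` is normalised to ``U`` and ``.`` to ``-``.
    A Stockholm ``#=GC SS_cons`` line, if present, is ignored with a notice:
    consensus structure annotation is an output of this package, never an input.
    """
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise EmptyInputError(f"{path}: empty file")
    if fmt == "auto":
        fmt = _sniff_format(text)
    if fmt not in _FORMATS:
        raise AlignmentError(f"unknown alignment format {fmt!r}")
    try:
        msa = AlignIO.read(io.StringIO(text), _FORMATS[fmt])
    except ValueError as exc:
        msg = str(exc)
        if "same length" in msg or "length" in msg.lower():
            raise RaggedAlignmentError(f"{path}: {msg}") from exc
        raise AlignmentError(f"{path}: {msg}") from exc
    if fmt == "stockholm" and "secondary_structure" in msa.column_annotations:
        log.info("%s: ignoring #=GC SS_cons annotation", path)
    ids = [rec.id for rec in msa]
    rows = [str(rec.seq) for rec in msa]
    if len({len(r) for r in rows}) > 1:
        raise RaggedAlignmentError(f"{path}: rows have differing lengths")
    return MultipleAlignment(ids, rows)


def write_alignment(aln: MultipleAlignment, path, fmt: str = "fasta") -> None:
    recs = [
        SeqRecord(Seq(r), id=t, description="")
        for t, r in zip(aln.taxon_ids, aln.rows)
    ]
    AlignIO.write(MultipleSeqAlignment(recs), str(path), _FORMATS[fmt])


@dataclass
class AlignmentPair:
    """The two family alignments restricted to shared taxa in matched order."""

    aln1: MultipleAlignment
    aln2: MultipleAlignment
    #: pairs of (taxon id in aln1, taxon id in aln2), in final row order
    taxon_map: list[tuple[str, str]]
    #: original 1-based columns kept in each part after all-gap removal
    kept_cols1: list[int] = field(default_factory=list)
    kept_cols2: list[int] = field(default_factory=list)

    @property
    def n_seqs(self) -> int:
        return self.aln1.n_seqs


def _prefix_key(taxon: str, sep: str) -> str:
    return taxon.split(sep, 1)[0]


def pair_taxa(
    aln1: MultipleAlignment,
    aln2: MultipleAlignment,
    policy: str = "exact_id",
    prefix_sep: str = "_",
    min_taxa: int = 2,
) -> AlignmentPair:
    """Match the rows of the two alignments to common organisms.

    ``exact_id`` matches identical ids, ``prefix`` matches on the id prefix
    before ``prefix_sep`` (useful when rows are named ``<organism>_<gene>``),
    and ``order`` pairs rows positionally.  Shared taxa keep the order of
    ``aln1``.  ``min_taxa`` may be lowered to 1 when evolutionary scoring is
    disabled.
    """
    if policy == "order":
        n = min(aln1.n_seqs, aln2.n_seqs)
        pairs = list(zip(aln1.taxon_ids[:n], aln2.taxon_ids[:n]))
    elif policy == "exact_id":
        shared = [t for t in aln1.taxon_ids if t in set(aln2.taxon_ids)]
        pairs = [(t, t) for t in shared]
    elif policy == "prefix":
        key2 = {}
        for t in aln2.taxon_ids:
            key2.setdefault(_prefix_key(t, prefix_sep), []).append(t)
        pairs = []
        for t in aln1.taxon_ids:
            k = _prefix_key(t, prefix_sep)
            if k in key2:
                if len(key2[k]) > 1:
                    raise PairingError(
                        f"prefix {k!r} is ambiguous in second alignment: {key2[k]}"
                    )
                pairs.append((t, key2[k][0]))
    else:
        raise ValueError(f"unknown pairing policy {policy!r}")
    if len(pairs) < min_taxa:
        raise PairingError(
            f"only {len(pairs)} taxa shared under policy {policy!r} "
            f"(need >= {min_taxa}); ids were {aln1.taxon_ids} vs {aln2.taxon_ids}"
        )
    r1, kept1 = aln1.restrict([a for a, _ in pairs])
    r2, kept2 = aln2.restrict([b for _, b in pairs])
    return AlignmentPair(r1, r2, pairs, kept1, kept2)


LINKER_DISPLAY = "&"
N_EVO_LINKER = 3  # number of prior-free linker columns in the evolutionary mode


@dataclass
class ConcatenatedAlignment:
    """Concatenation of the two parts with a linker.

    ``display`` mode inserts a single ``&`` column (the cofolding rendering
    convention); ``evo`` mode inserts :data:`N_EVO_LINKER` prior-free columns
    used by the constrained phylo-SCFG.  Logical numbering of the columns of
    part 2 starts at ``L1 + 1`` in both modes — linker columns are excluded
    from the logical numbering.
    """

    parent: AlignmentPair
    mode: str = "display"

    def __post_init__(self):
        if self.mode not in ("display", "evo"):
            raise ValueError(f"unknown concatenation mode {self.mode!r}")
        self.L1 = self.parent.aln1.length
        self.L2 = self.parent.aln2.length
        self.n_linker = 1 if self.mode == "display" else N_EVO_LINKER

    @property
    def n_seqs(self) -> int:
        return self.parent.n_seqs

    @property
    def logical_length(self) -> int:
        """Number of real columns (linker excluded): L1 + L2."""
        return self.L1 + self.L2

    @property
    def physical_length(self) -> int:
        return self.L1 + self.n_linker + self.L2

    def physical_rows(self, linker_char: str | None = None) -> list[str]:
        ch = linker_char if linker_char is not None else (
            LINKER_DISPLAY if self.mode == "display" else "-"
        )
        link = ch * self.n_linker
        return [
            r1 + link + r2
            for r1, r2 in zip(self.parent.aln1.rows, self.parent.aln2.rows)
        ]

    def col_of_part2(self, j: int) -> int:
        """Logical global column of column ``j`` (1-based) of part 2."""
        if not 1 <= j <= self.L2:
            raise IndexError(f"part-2 column {j} outside 1..{self.L2}")
        return self.L1 + j

    def part_of(self, col: int):
        """Part of a *physical* column: 1, 2 or ``'linker'``."""
        if 1 <= col <= self.L1:
            return 1
        if self.L1 < col <= self.L1 + self.n_linker:
            return "linker"
        if col <= self.physical_length:
            return 2
        raise IndexError(f"column {col} outside 1..{self.physical_length}")

    def logical_to_physical(self, col: int) -> int:
        """Map logical column (1..L1+L2) to physical column."""
        if not 1 <= col <= self.logical_length:
            raise IndexError(f"logical column {col} outside 1..{self.logical_length}")
        return col if col <= self.L1 else col + self.n_linker

    def physical_to_logical(self, col: int):
        """Map physical column to logical column, or ``None`` on the linker."""
        part = self.part_of(col)
        if part == "linker":
            return None
        return col if part == 1 else col - self.n_linker

    def prior_free_physical(self) -> list[int]:
        """Physical columns of the linker (prior-free in the evolutionary model)."""
        return list(range(self.L1 + 1, self.L1 + self.n_linker + 1))

    def to_alignment(self, linker_as: str = "N") -> MultipleAlignment:
        """Concatenation as a plain alignment, linker written as ``linker_as``.

        With the default ``"N"`` the linker columns carry no phylogenetic
        signal, so the same object serves tree estimation from the
        concatenated alignment.
        """
        return MultipleAlignment(
            [a for a, _ in self.parent.taxon_map]
            if len(set(a for a, _ in self.parent.taxon_map)) == self.n_seqs
            else [f"{a}&{b}" for a, b in self.parent.taxon_map],
            self.physical_rows(linker_char=linker_as),
        )


def concatenate(pair: AlignmentPair, mode: str = "display") -> ConcatenatedAlignment:
    return ConcatenatedAlignment(pair, mode)
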