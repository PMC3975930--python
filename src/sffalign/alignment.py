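"""Pairwise alignment representation, repeat annotation and blocks.

An alignment of X (length n) and Y (length m) is a sequence of columns.
Each column either aligns x_i with y_j (a match column), or aligns one
symbol with a gap. A gap is annotated with the position of the nearest
non-gap symbol on its left, so a column is one of::

    (i, j)         match column
    (i, -_j)       x_i aligned to a gap placed after y_j
    (-_i, j)       y_j aligned to a gap placed after x_i

Gap-against-gap columns are forbidden. Internally an alignment is stored as
a sequence of moves (0 = match, 1 = consume X, 2 = consume Y) from which the
column notation is derived; explicit column lists use plain integers for
positions (1-based) and ``("-", j)`` tuples for annotated gaps.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import FormatError, InputError

MATCH, XGAP, YGAP = 0, 1, 2  # move codes; XGAP consumes X against a gap in Y

GAP_CHAR = "-"


class Alignment:
    """A valid pairwise alignment stored as a move sequence."""

    __slots__ = ("moves",)

    def __init__(self, moves: Iterable[int]):
        self.moves = np.asarray(list(moves) if not isinstance(moves, np.ndarray)
                                else moves, dtype=np.int8)
        if self.moves.size and (self.moves.min() < 0 or self.moves.max() > 2):
            raise InputError("moves must be 0 (match), 1 (X-gap) or 2 (Y-gap)")

    @property
    def n(self) -> int:
        return int(np.count_nonzero(self.moves != YGAP))

    @property
    def m(self) -> int:
        return int(np.count_nonzero(self.moves != XGAP))

    def __len__(self) -> int:
        return len(self.moves)

    def __eq__(self, other) -> bool:
        return isinstance(other, Alignment) and \
            np.array_equal(self.moves, other.moves)

    def __repr__(self) -> str:
        return f"Alignment({len(self)} columns, n={self.n}, m={self.m})"

    def columns(self) -> list[tuple]:
        """Columns in annotated-gap notation (1-based positions)."""
        out = []
        i = j = 0
        for mv in self.moves:
            if mv == MATCH:
                i += 1
                j += 1
                out.append((i, j))
            elif mv == XGAP:
                i += 1
                out.append((i, (GAP_CHAR, j)))
            else:
                j += 1
                out.append(((GAP_CHAR, i), j))
        return out

    def column_keys(self) -> set[tuple]:
        """Hashable identity of every column, gap annotation included."""
        out = set()
        i = j = 0
        for mv in self.moves:
            if mv == MATCH:
                i += 1
                j += 1
            elif mv == XGAP:
                i += 1
            else:
                j += 1
            out.add((int(mv), i, j))
        return out

    def cells(self) -> list[tuple[int, int]]:
        """Lattice cells (i, j) visited by the alignment path, incl. (0, 0)."""
        out = [(0, 0)]
        i = j = 0
        for mv in self.moves:
            if mv != YGAP:
                i += 1
            if mv != XGAP:
                j += 1
            out.append((i, j))
        return out


@dataclass
class RepeatAnnotation:
    """Per-column binary labels: 1 = generated by a repeat submodel."""

    labels: np.ndarray

    def __init__(self, labels):
        self.labels = np.asarray(list(labels) if not isinstance(labels, np.ndarray)
                                 else labels, dtype=np.int8)

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other) -> bool:
        return isinstance(other, RepeatAnnotation) and \
            np.array_equal(self.labels, other.labels)


@dataclass(frozen=True)
class Block:
    """A pair of intervals (0-based half-open) with a repeat label.

    Non-repeat blocks hold exactly one column; repeat blocks cover a maximal
    run of repeat-labeled columns.
    """

    x: tuple[int, int]
    y: tuple[int, int]
    label: int


# --------------------------------------------------------------- conversion
def from_gapped_strings(row_x: str, row_y: str) -> Alignment:
    """Build an alignment from two equal-length gapped rows."""
    if len(row_x) != len(row_y):
        raise FormatError(
            f"gapped rows have different lengths ({len(row_x)} vs {len(row_y)})")
    moves = []
    for k, (a, b) in enumerate(zip(row_x, row_y)):
        ag = a == GAP_CHAR
        bg = b == GAP_CHAR
        if ag and bg:
            raise FormatError(f"gap-against-gap column at index {k}")
        moves.append(YGAP if ag else (XGAP if bg else MATCH))
    return Alignment(moves)


def to_gapped_strings(aln: Alignment, X: str, Y: str) -> tuple[str, str]:
    """Render the alignment as two gapped rows over the given sequences."""
    if len(X) != aln.n or len(Y) != aln.m:
        raise InputError("sequence lengths do not match the alignment")
    rx, ry = [], []
    i = j = 0
    for mv in aln.moves:
        if mv == MATCH:
            rx.append(X[i]); ry.append(Y[j]); i += 1; j += 1
        elif mv == XGAP:
            rx.append(X[i]); ry.append(GAP_CHAR); i += 1
        else:
            rx.append(GAP_CHAR); ry.append(Y[j]); j += 1
    return "".join(rx), "".join(ry)


def validate_alignment(aln, n: int, m: int) -> list[str]:
    """Check alignment invariants; empty list iff valid.

    Accepts either an :class:`Alignment` or an explicit column list in
    annotated-gap notation.
    """
    if isinstance(aln, Alignment):
        cols = aln.columns()
    else:
        cols = list(aln)
    out = []
    i = j = 0  # last consumed positions
    for t, (a, b) in enumerate(cols):
        a_gap = isinstance(a, tuple)
        b_gap = isinstance(b, tuple)
        if a_gap and b_gap:
            out.append(f"column {t + 1} aligns a gap with a gap")
            continue
        if a_gap:
            if a[1] != i:
                out.append(f"column {t + 1}: gap in X anchored at {a[1]}, expected {i}")
        else:
            if a != i + 1:
                out.append(f"column {t + 1}: X position {a}, expected {i + 1}")
            i = a if isinstance(a, int) else i
        if b_gap:
            if b[1] != j:
                out.append(f"column {t + 1}: gap in Y anchored at {b[1]}, expected {j}")
        else:
            if b != j + 1:
                out.append(f"column {t + 1}: Y position {b}, expected {j + 1}")
            j = b if isinstance(b, int) else j
    if i != n:
        out.append(f"alignment consumes {i} of {n} X symbols")
    if j != m:
        out.append(f"alignment consumes {j} of {m} Y symbols")
    return out


# --------------------------------------------------------------- annotation
def alignment_from_state_path(model, path: Sequence[str], n: int, m: int) -> Alignment:
    """Derive the alignment generated by a state path (silent states skipped)."""
    from .hmm import EmissionClass

    moves = []
    for s in path:
        cls = model.emission_class.get(s)
        if cls is None:
            raise InputError(f"unknown state {s!r} in path")
        if cls == EmissionClass.BOTH:
            moves.append(MATCH)
        elif cls == EmissionClass.X_ONLY:
            moves.append(XGAP)
        elif cls == EmissionClass.Y_ONLY:
            moves.append(YGAP)
    aln = Alignment(moves)
    if aln.n != n or aln.m != m:
        raise InputError("state path does not generate sequences of the given lengths")
    return aln


def repeat_annotation_from_states(model, path: Sequence[str]) -> RepeatAnnotation:
    """Per-column repeat labels from the emitting states of a path."""
    from .hmm import EmissionClass

    labels = []
    for s in path:
        cls = model.emission_class.get(s)
        if cls is None:
            raise InputError(f"unknown state {s!r} in path")
        if cls != EmissionClass.SILENT:
            labels.append(1 if model.is_repeat_state(s) else 0)
    return RepeatAnnotation(labels)


def blocks_from_annotation(aln: Alignment, ann: RepeatAnnotation) -> list[Block]:
    """Split an annotated alignment into blocks.

    Maximal runs of repeat-labeled columns form one block each; every
    non-repeat column is its own block. Blocks tile [0, n) x [0, m).
    """
    if len(aln) != len(ann):
        raise InputError(
            f"annotation length {len(ann)} != alignment length {len(aln)}")
    blocks = []
    i = j = 0
    t = 0
    labels = ann.labels
    moves = aln.moves
    while t < len(moves):
        if labels[t]:
            xi, yj = i, j
            while t < len(moves) and labels[t]:
                if moves[t] != YGAP:
                    i += 1
                if moves[t] != XGAP:
                    j += 1
                t += 1
            blocks.append(Block((xi, i), (yj, j), 1))
        else:
            xi, yj = i, j
            if moves[t] != YGAP:
                i += 1
            if moves[t] != XGAP:
                j += 1
            blocks.append(Block((xi, i), (yj, j), 0))
            t += 1
    return blocks


def annotation_intervals(aln: Alignment, ann: RepeatAnnotation
                         ) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Project repeat-labeled columns to per-sequence base intervals.

    Returns 0-based half-open interval lists for X and for Y (merged runs of
    repeat-labeled bases).
    """
    lab_x = np.zeros(aln.n, dtype=bool)
    lab_y = np.zeros(aln.m, dtype=bool)
    i = j = 0
    for mv, lab in zip(aln.moves, ann.labels):
        if mv != YGAP:
            if lab:
                lab_x[i] = True
            i += 1
        if mv != XGAP:
            if lab:
                lab_y[j] = True
            j += 1
    return _runs(lab_x), _runs(lab_y)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out


# ----------------------------------------------------------------------- IO
def read_gapped_fasta(path) -> tuple[tuple[str, str], tuple[str, str]]:
    """Read a two-record gapped FASTA; returns ((name_x, row_x), (name_y, row_y))."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise FormatError(
            f"{path}: expected exactly 2 records, found {len(records)}")
    (rx, ry) = records
    if len(rx.seq) != len(ry.seq):
        raise FormatError(f"{path}: rows have different lengths")
    return (rx.id, str(rx.seq).upper()), (ry.id, str(ry.seq).upper())


def write_gapped_fasta(path, name_x: str, row_x: str, name_y: str, row_y: str) -> None:
    with open(path, "w") as fh:
        for name, row in ((name_x, row_x), (name_y, row_y)):
            fh.write(f">{name}\n")
            for k in range(0, len(row), 60):
                fh.write(row[k:k + 60] + "\n")


def write_bed(path, chrom: str, intervals, names=None) -> None:
    """Write 0-based half-open intervals as BED3 (+name column if given)."""
    with open(path, "w") as fh:
        for k, (a, b) in enumerate(intervals):
            if names is not None:
                fh.write(f"{chrom}\t{a}\t{b}\t{names[k]}\n")
            else:
                fh.write(f"{chrom}\t{a}\t{b}\n")


def read_bed(path) -> list[tuple[str, int, int, str | None]]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: not a BED interval")
            try:
                a, b = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer coordinates") from exc
            out.append((parts[0], a, b, parts[3] if len(parts) > 3 else None))
    return out
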