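"""Practical machinery for aligning long regions.

* banding around a guide alignment (Chebyshev window on the lattice),
* parsing Tandem Repeats Finder ``.dat`` output,
* SRF reannotation: re-scanning both sequences with every discovered
  consensus so a repeat found in only one sequence also contributes a
  candidate interval in the other,
* motif-library restriction to observed consensuses (original entry
  probabilities kept; novel consensuses enter at the minimum prior),
* realignment of repeat blocks (plus adjacent gap runs) with the plain
  three-state model,
* window-based realignment of a long guide alignment.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .alignment import (MATCH, XGAP, YGAP, Alignment, RepeatAnnotation,
                        blocks_from_annotation)
from .errors import FormatError, InputError, ParameterError
from .hmm import viterbi_path
from .models import (MotifLibrary, SffModel, SunflowerParams,
                     ThreeStateParams, build_srf, build_three_state)

DEFAULT_BAND_WIDTH = 30
DEFAULT_CANDIDATE_TOL = 10


# ------------------------------------------------------------------ banding
@dataclass
class BandMask:
    """Per-row allowed j-interval around a guide alignment path."""

    lo: np.ndarray   # (n+1,) inclusive
    hi: np.ndarray   # (n+1,) inclusive
    m: int

    def to_array(self, n: int, m: int) -> np.ndarray:
        if len(self.lo) != n + 1 or self.m != m:
            raise InputError("band mask does not match sequence lengths")
        allowed = np.zeros((n + 1, m + 1), dtype=np.uint8)
        for i in range(n + 1):
            allowed[i, self.lo[i]:self.hi[i] + 1] = 1
        return allowed

    def contains_path(self, aln: Alignment) -> bool:
        return all(self.lo[i] <= j <= self.hi[i] for i, j in aln.cells())


def band_mask(guide: Alignment, width: int) -> BandMask:
    """Allow cell (i, j) iff it lies within Chebyshev distance ``width`` of
    some cell on the guide alignment's lattice path."""
    n, m = guide.n, guide.m
    jmin = np.full(n + 1, m + 1, dtype=np.int64)
    jmax = np.full(n + 1, -1, dtype=np.int64)
    for i, j in guide.cells():
        jmin[i] = min(jmin[i], j)
        jmax[i] = max(jmax[i], j)
    lo = np.empty(n + 1, dtype=np.int64)
    hi = np.empty(n + 1, dtype=np.int64)
    for i in range(n + 1):
        a = max(0, i - width)
        b = min(n, i + width)
        lo[i] = max(0, int(jmin[a:b + 1].min()) - width)
        hi[i] = min(m, int(jmax[a:b + 1].max()) + width)
    return BandMask(lo, hi, m)


# -------------------------------------------------------------- TRF parsing
@dataclass(frozen=True)
class TrfRecord:
    interval: tuple[int, int]   # 0-based half-open
    period: int
    copy_number: float
    consensus: str


_TRF_HEADER_PREFIXES = ("Tandem Repeats Finder", "Gary Benson", "Program",
                        "Version", "Sequence:", "Parameters:")


def parse_trf_dat(text: str) -> list[TrfRecord]:
    """Parse Tandem Repeats Finder ``.dat`` table output.

    Data lines hold 15 whitespace-separated fields starting with the
    1-based inclusive start and end of the repeat; field 3 is the period,
    field 4 the copy number and field 14 the consensus motif.
    """
    records = []
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(_TRF_HEADER_PREFIXES):
            continue
        parts = line.split()
        if len(parts) < 14:
            raise FormatError(f"line {ln}: expected a 15-field record")
        try:
            start, end = int(parts[0]), int(parts[1])
            period = int(parts[2])
            copies = float(parts[3])
            consensus = parts[13].upper()
        except ValueError as exc:
            raise FormatError(f"line {ln}: malformed record") from exc
        if start < 1 or end < start:
            raise FormatError(f"line {ln}: bad coordinates {start}..{end}")
        records.append(TrfRecord((start - 1, end), period, copies, consensus))
    return records


# --------------------------------------------------------- SRF reannotation
@dataclass
class RepeatIntervalSets:
    """Candidate repeat intervals per sequence with their consensus motifs.

    Lists, not sets: intervals are "not necessarily disjoint" and duplicates
    from different consensuses are kept.
    """

    t_x: list[tuple[int, int, str]] = field(default_factory=list)
    t_y: list[tuple[int, int, str]] = field(default_factory=list)

    def intervals(self, side: str) -> list[tuple[int, int]]:
        src = self.t_x if side == "X" else self.t_y
        return [(a, b) for a, b, _ in src]

    def consensuses(self) -> list[str]:
        return sorted({c for _, _, c in self.t_x + self.t_y})


def srf_intervals(consensus: str, seq: str,
                  params: SunflowerParams | None = None,
                  background: np.ndarray | None = None,
                  stay: float = 0.99, enter: float = 0.005
                  ) -> list[tuple[int, int]]:
    """Maximal runs of sunflower states in the SRF Viterbi annotation."""
    model = build_srf(consensus, params, background, stay, enter)
    path, logp = viterbi_path(model, seq, "")
    out = []
    pos = 0
    start = None
    for s in path:
        if not model.is_emitting(s):
            continue
        if model.is_repeat_state(s):
            if start is None:
                start = pos
        else:
            if start is not None:
                out.append((start, pos))
                start = None
        pos += 1
    if start is not None:
        out.append((start, pos))
    return out


def srf_reannotate(consensus_set: Iterable[str], X: str, Y: str,
                   params: SunflowerParams | None = None,
                   background: np.ndarray | None = None,
                   initial: RepeatIntervalSets | None = None,
                   stay: float = 0.99, enter: float = 0.005
                   ) -> RepeatIntervalSets:
    """Annotate candidate repeat intervals in both sequences.

    For every consensus, the SRF Viterbi annotation of each sequence is
    appended to T_X/T_Y, so a repeat discovered in one sequence has a chance
    to contribute the orthologous interval in the other.
    """
    out = RepeatIntervalSets(
        list(initial.t_x) if initial else [],
        list(initial.t_y) if initial else [])
    for consensus in sorted(set(c.upper() for c in consensus_set)):
        for a, b in srf_intervals(consensus, X, params, background, stay, enter):
            out.t_x.append((a, b, consensus))
        for a, b in srf_intervals(consensus, Y, params, background, stay, enter):
            out.t_y.append((a, b, consensus))
    return out


# ------------------------------------------------------ library restriction
def restrict_library(library: MotifLibrary,
                     observed_consensuses: Iterable[str],
                     floor_policy: str = "min") -> MotifLibrary:
    """Restrict the SFF to observed motifs.

    Kept motifs retain their original entry probabilities (the unused mass
    returns to the three-state core rather than being renormalized); a
    consensus not in the library is added at the minimum prior of the full
    library (``floor_policy="min"``, the only policy offered).
    """
    if floor_policy != "min":
        raise ParameterError(f"unknown floor policy {floor_policy!r}")
    observed = {c.upper() for c in observed_consensuses}
    prior = dict(library.motifs)
    floor = min(prior.values()) if prior else 1.0
    kept = [(c, prior.get(c, floor)) for c in sorted(observed)]
    out = MotifLibrary.__new__(MotifLibrary)
    out.motifs = kept  # deliberately unnormalized: mass goes back to the core
    return out


def restricted_sff(sff: SffModel, observed_consensuses: Iterable[str]) -> SffModel:
    """SFF model over the restricted library.

    The total motif-entry probability is scaled by the kept prior mass so
    every kept motif keeps exactly its original hub entry probability.
    """
    sub = restrict_library(sff.library, observed_consensuses)
    mass = sum(w for _, w in sub.motifs)
    sun = SunflowerParams(**{**sff.sunflower.__dict__})
    sun.motif_entry = sff.sunflower.motif_entry * mass
    if mass > 0:
        norm = MotifLibrary([(c, w / mass) for c, w in sub.motifs])
    else:
        norm = MotifLibrary([])
    return SffModel(norm, sff.three_state, sun)


# ------------------------------------------------------------- realignment
def realign_repeat_blocks(aln: Alignment, ann: RepeatAnnotation,
                          X: str, Y: str,
                          three_state: ThreeStateParams | None = None
                          ) -> tuple[Alignment, RepeatAnnotation]:
    """Realign repeat blocks (with adjacent gap runs) by the three-state PHMM.

    Each maximal run of repeat-labeled columns, extended left and right by
    the flanking maximal runs of gap columns, is replaced by the three-state
    Viterbi alignment of the covered substrings. Labels: realigned columns
    keep label 1 where they cover former repeat columns' bases, but since
    the realignment mixes bases freely the whole replaced stretch is
    relabeled 1 when it contained any repeat column.
    """
    if len(aln) != len(ann):
        raise InputError("annotation length mismatch")
    model = build_three_state(three_state or ThreeStateParams())
    moves = aln.moves
    labels = ann.labels
    t = len(moves)
    out_moves: list[int] = []
    out_labels: list[int] = []
    i = j = 0
    k = 0
    while k < t:
        if not labels[k]:
            out_moves.append(int(moves[k]))
            out_labels.append(0)
            if moves[k] != YGAP:
                i += 1
            if moves[k] != XGAP:
                j += 1
            k += 1
            continue
        # extend the repeat run over adjacent gap columns on the left
        # (i, j keep counting original columns; the absorbed columns only
        # move the region start back)
        dx = dy = 0
        while out_moves and out_moves[-1] != MATCH and not out_labels[-1]:
            mv = out_moves.pop()
            out_labels.pop()
            if mv != YGAP:
                dx += 1
            if mv != XGAP:
                dy += 1
        x0, y0 = i - dx, j - dy
        while k < t and labels[k]:
            if moves[k] != YGAP:
                i += 1
            if moves[k] != XGAP:
                j += 1
            k += 1
        # extend over adjacent gap columns on the right
        while k < t and not labels[k] and moves[k] != MATCH:
            if moves[k] != YGAP:
                i += 1
            if moves[k] != XGAP:
                j += 1
            k += 1
        sub_x = X[x0:i]
        sub_y = Y[y0:j]
        path, _ = viterbi_path(model, sub_x, sub_y)
        sub_moves = [0 if model.emission_class[s].name == "BOTH"
                     else (1 if model.emission_class[s].name == "X_ONLY" else 2)
                     for s in path if model.is_emitting(s)]
        out_moves.extend(sub_moves)
        out_labels.extend([1] * len(sub_moves))
    return Alignment(out_moves), RepeatAnnotation(out_labels)


# -------------------------------------------------------- window realignment
@dataclass
class Window:
    """A realignment window: column range of the guide and the covered
    substring intervals."""

    cols: tuple[int, int]
    x: tuple[int, int]
    y: tuple[int, int]
    has_repeat: bool


def split_windows(guide: Alignment, intervals: RepeatIntervalSets,
                  margin: int = 20) -> list[Window]:
    """Split a guide alignment into non-overlapping windows.

    Boundaries are placed at match columns whose bases lie outside every
    candidate repeat interval and at least ``margin`` columns away from any
    repeat-overlapping column, so windows never cut through a repeat.
    Consecutive boundary columns delimit one window; windows are flagged by
    whether they overlap any candidate interval.
    """
    t = len(guide)
    in_rep_x = np.zeros(guide.n + 1, dtype=bool)
    for a, b in intervals.intervals("X"):
        in_rep_x[a:b] = True
    in_rep_y = np.zeros(guide.m + 1, dtype=bool)
    for a, b in intervals.intervals("Y"):
        in_rep_y[a:b] = True
    col_rep = np.zeros(t, dtype=bool)
    i = j = 0
    match_col = np.zeros(t, dtype=bool)
    for k, mv in enumerate(guide.moves):
        if mv != YGAP:
            if in_rep_x[i]:
                col_rep[k] = True
            i += 1
        if mv != XGAP:
            if in_rep_y[j]:
                col_rep[k] = True
            j += 1
        match_col[k] = mv == MATCH
    near = np.zeros(t, dtype=bool)
    rep_idx = np.flatnonzero(col_rep)
    for k in rep_idx:
        near[max(0, k - margin):k + margin + 1] = True
    boundaries = [k for k in range(t) if match_col[k] and not near[k]]
    cuts = [0] + [k + 1 for k in boundaries if 0 < k + 1 < t] + [t]
    cuts = sorted(set(cuts))
    cells = guide.cells()
    windows = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        (x0, y0), (x1, y1) = cells[a], cells[b]
        windows.append(Window((a, b), (x0, x1), (y0, y1),
                              bool(col_rep[a:b].any())))
    return windows


def window_realign(guide: Alignment, X: str, Y: str,
                   intervals: RepeatIntervalSets,
                   decoder: Callable[..., object],
                   margin: int = 20,
                   realign_all: bool = False
                   ) -> tuple[Alignment, RepeatAnnotation]:
    """Realign a long guide alignment window by window.

    ``decoder(X_sub, Y_sub, window_intervals)`` must return an object with
    ``alignment`` and ``annotation`` attributes (e.g. a decode result).
    Windows without candidate repeat intervals keep the guide columns unless
    ``realign_all`` is set. The re-spliced alignment covers exactly the
    original sequences.
    """
    windows = split_windows(guide, intervals, margin)
    out_moves: list[int] = []
    out_labels: list[int] = []
    for w in windows:
        if not (w.has_repeat or realign_all):
            seg = guide.moves[w.cols[0]:w.cols[1]]
            out_moves.extend(int(v) for v in seg)
            out_labels.extend([0] * len(seg))
            continue
        local = RepeatIntervalSets(
            [(max(a, w.x[0]) - w.x[0], min(b, w.x[1]) - w.x[0], c)
             for a, b, c in intervals.t_x if a < w.x[1] and b > w.x[0]],
            [(max(a, w.y[0]) - w.y[0], min(b, w.y[1]) - w.y[0], c)
             for a, b, c in intervals.t_y if a < w.y[1] and b > w.y[0]])
        res = decoder(X[w.x[0]:w.x[1]], Y[w.y[0]:w.y[1]], local)
        sub_aln = res.alignment
        if sub_aln.n != w.x[1] - w.x[0] or sub_aln.m != w.y[1] - w.y[0]:
            raise AssertionError("window realignment does not splice")
        out_moves.extend(int(v) for v in sub_aln.moves)
        out_labels.extend(int(v) for v in res.annotation.labels)
    return Alignment(out_moves), RepeatAnnotation(out_labels)
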