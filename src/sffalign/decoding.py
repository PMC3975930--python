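"""Column-level decoders as maximum-expected-gain procedures.

All three criteria score an alignment column by column:

* ``viterbi`` — the single most probable state path (gain 1 only for a
  completely correct alignment plus state annotation),
* ``posterior`` — each repeat-labeled column earns its posterior
  probability; the decoder returns the compatible column set with the
  highest total posterior,
* ``marginalized`` — like posterior, but the posterior of a gap column
  (i, -_j) is first summed over all gap placements (i, -_l), and
  symmetrically for gaps in X.

Columns are labeled with the repeat annotation (label 1 = emitted by a
repeat submodel state); posteriors are summed over all states sharing a
column kind and label.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _engine
from .alignment import (MATCH, XGAP, YGAP, Alignment, RepeatAnnotation,
                        alignment_from_state_path,
                        repeat_annotation_from_states)
from .errors import InputError, ZeroProbabilityError
from .hmm import PairHMM, _prepare, viterbi_path

CRITERIA = ("viterbi", "posterior", "marginalized")


@dataclass
class ColumnGainTable:
    """Per-cell, per-column-kind, per-label gains (linear space).

    Arrays have shape (2, n+1, m+1): index 0/1 is the repeat label. The
    match entry at (i, j) refers to the column aligning x_i with y_j; the
    xgap entry to the column placing x_i after y_j; ygap symmetrically.
    """

    match: np.ndarray
    xgap: np.ndarray
    ygap: np.ndarray
    gap_marginalized: bool = False

    @property
    def n(self) -> int:
        return self.match.shape[1] - 1

    @property
    def m(self) -> int:
        return self.match.shape[2] - 1

    def copy(self) -> "ColumnGainTable":
        return ColumnGainTable(self.match.copy(), self.xgap.copy(),
                               self.ygap.copy(), self.gap_marginalized)


def labeled_column_posteriors(model: PairHMM, X, Y, band=None) -> ColumnGainTable:
    """Column posteriors marginalized over states with the same repeat label.

    Uses a full backward lattice plus a streaming forward pass, so memory is
    one per-state table rather than two.
    """
    comp, x, y, allowed = _prepare(model, X, Y, band)
    n, m = len(x), len(y)
    ns = len(comp.cls)
    # backward in row blocks of ~sqrt(n): memory O(sqrt(n) * m * n_states)
    C = max(1, int(math.isqrt(n + 1)) + 1)
    dummy = np.full((m + 1, ns), _engine.NEG_INF)

    def rows(hi, lo, above, has):
        return _engine.backward_rows_kernel(
            comp.cls, comp.ctxk, comp.le_pair, comp.le_single, comp.proc_bwd,
            comp.out_ptr, comp.out_dst, comp.out_logp, comp.end,
            x, y, allowed, hi, lo, above, has)

    checkpoints: dict[int, np.ndarray] = {}
    blocks: list[tuple[int, int]] = []
    hi = n
    above = dummy
    has = False
    while hi >= 0:
        lo = max(0, hi - C + 1)
        blocks.append((lo, hi))
        block = rows(hi, lo, above, has)
        checkpoints[lo] = block[0].copy()
        above = checkpoints[lo]
        has = True
        hi = lo - 1
    log_total = float(checkpoints[0][0, comp.start])
    if log_total == _engine.NEG_INF:
        raise ZeroProbabilityError("model assigns zero probability to (X, Y)")
    gid = np.where(comp.cls == _engine.CLS_SILENT, -1,
                   2 * comp.cls.astype(np.int64) + comp.repeat)
    P = np.zeros((6, n + 1, m + 1))
    Fprev = np.full((m + 1, ns), _engine.NEG_INF)
    for lo, hi in reversed(blocks):
        if hi == n:
            block = rows(hi, lo, dummy, False)
        else:
            block = rows(hi, lo, checkpoints[hi + 1], True)
        _engine.grouped_forward_rows_kernel(
            comp.cls, comp.ctxk, comp.le_pair, comp.le_single, comp.proc_fwd,
            comp.tin_ptr, comp.tin_src, comp.tin_logp, comp.start,
            gid, block, log_total, x, y, allowed, lo, hi, Fprev, P)
    return ColumnGainTable(match=P[0:2], xgap=P[2:4], ygap=P[4:6])


def marginalize_gap_columns(table: ColumnGainTable) -> ColumnGainTable:
    """Replace each gap-column gain with its sum over gap placements.

    The X-gap entry at (i, j, label) becomes the sum over all l of the
    entries (i, l, label); symmetrically for Y gaps. Match entries are
    untouched. The table records that its gap rows are already marginal
    sums, which makes the operation idempotent.
    """
    if table.gap_marginalized:
        return table.copy()
    out = table.copy()
    out.xgap[:] = table.xgap.sum(axis=2, keepdims=True)
    out.ygap[:] = table.ygap.sum(axis=1, keepdims=True)
    out.gap_marginalized = True
    return out


def best_column_chain(table: ColumnGainTable, n: int | None = None,
                      m: int | None = None):
    """Maximum-total-gain valid labeled alignment.

    Returns (alignment, annotation, total gain). Each column's label is
    chosen independently (the larger gain wins, label 0 on ties); ties
    between column kinds prefer match over X-gap over Y-gap.
    """
    n = table.n if n is None else n
    m = table.m if m is None else m
    if (n, m) != (table.n, table.m):
        raise InputError("gain table does not match sequence lengths")
    lab_m = (table.match[1] > table.match[0]).astype(np.int8)
    lab_x = (table.xgap[1] > table.xgap[0]).astype(np.int8)
    lab_y = (table.ygap[1] > table.ygap[0]).astype(np.int8)
    gm = np.maximum(table.match[0], table.match[1])
    gx = np.maximum(table.xgap[0], table.xgap[1])
    gy = np.maximum(table.ygap[0], table.ygap[1])
    total, mv = _engine.chain_kernel(gm, gx, gy)
    moves = []
    labels = []
    i, j = n, m
    while i > 0 or j > 0:
        k = mv[i, j]
        if k < 0:
            raise InputError("gain table admits no valid alignment")
        moves.append(int(k))
        if k == MATCH:
            labels.append(int(lab_m[i, j]))
            i, j = i - 1, j - 1
        elif k == XGAP:
            labels.append(int(lab_x[i, j]))
            i -= 1
        else:
            labels.append(int(lab_y[i, j]))
            j -= 1
    moves.reverse()
    labels.reverse()
    return Alignment(moves), RepeatAnnotation(labels), float(total)


@dataclass
class DecodeResult:
    alignment: Alignment
    annotation: RepeatAnnotation
    criterion: str
    score: float                     # log-probability (viterbi) or total gain
    state_path: list[str] | None = None


def decode(model: PairHMM, X, Y, criterion: str = "marginalized",
           band=None) -> DecodeResult:
    """Decode a sequence pair under one of the column-level criteria."""
    if criterion not in CRITERIA:
        raise InputError(f"unknown criterion {criterion!r}; pick from {CRITERIA}")
    if criterion == "viterbi":
        path, logp = viterbi_path(model, X, Y, band)
        if not path and (len(X) or len(Y)):
            raise ZeroProbabilityError("no state path generates (X, Y)")
        aln = alignment_from_state_path(model, path, len(X), len(Y))
        ann = repeat_annotation_from_states(model, path)
        return DecodeResult(aln, ann, criterion, logp, state_path=path)
    table = labeled_column_posteriors(model, X, Y, band)
    if criterion == "marginalized":
        table = marginalize_gap_columns(table)
    aln, ann, gain = best_column_chain(table)
    return DecodeResult(aln, ann, criterion, gain)
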