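"""Generalized (block) decoding of the SFF model.

The SFF is transformed into a generalized pair HMM in which all repeat
states collapse into one generalized state R emitting an entire repeat
block: a pair of substrings, the X part followed by the Y part. Because the
X-side sunflower of motif i hands over to its Y-side twin with probability
one, the block emission factorizes as

    Pr(x, y | R) = sum_i prior_i * Pr(x | R_iX) * Pr(y | R_iY)

which is computed from per-motif substring probability tables
(one forward sweep per start position, O((n^2 + m^2) E) total).

Block decoding maximizes the expected gain where each candidate repeat
block earns its posterior probability times its number of non-gap symbols
(|x| + |y|) and each non-repeat column earns its label-0 posterior; block
Viterbi decoding finds the most probable block structure (summing over
motifs and internal paths inside each repeat block).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numba import njit
from scipy.special import logsumexp

from . import _engine
from ._alphabet import encode
from .alignment import (MATCH, XGAP, YGAP, Alignment, Block,
                        RepeatAnnotation)
from .errors import InputError, ModelError, ZeroProbabilityError
from .hmm import PairHMM
from .models import SffModel

NEG_INF = _engine.NEG_INF


# ------------------------------------------------------- substring tables
def substring_probs(fragment: PairHMM, S: str | np.ndarray) -> np.ndarray:
    """log Pr(S[a:b) | fragment) for every interval [a, b).

    The fragment is a single-sequence HMM (emitting states on the X side)
    with silent entry and exit; entry [a, b] of the returned (n+1, n+1)
    array is the log-probability that one pass through the fragment emits
    exactly the substring S[a:b). Entries with b < a are -inf; [a, a) holds
    the fragment's empty-emission probability.
    """
    comp = fragment.compiled()
    if np.any(comp.cls == _engine.CLS_BOTH) or np.any(comp.cls == _engine.CLS_Y):
        raise ModelError("substring tables require a single-sequence fragment")
    s = S if isinstance(S, np.ndarray) else encode(S)
    return _engine.substring_forward_kernel(
        comp.cls, comp.ctxk, comp.le_single, comp.proc_fwd, comp.tin_ptr,
        comp.tin_src, comp.tin_logp, comp.start, comp.end, s)


@dataclass
class SubstringProbTable:
    """Per-motif substring probabilities for both sequences of an instance."""

    log_priors: np.ndarray           # (k,)
    x_tables: list[np.ndarray]       # per motif, (n+1, n+1)
    y_tables: list[np.ndarray]       # per motif, (m+1, m+1)

    @classmethod
    def build(cls, sff: SffModel, X, Y) -> "SubstringProbTable":
        with np.errstate(divide="ignore"):
            lp = np.log(sff.library.priors)
        xt = [substring_probs(sff.x_fragment(i), X)
              for i in range(len(sff.library))]
        yt = [substring_probs(sff.y_fragment(i), Y)
              for i in range(len(sff.library))]
        return cls(lp, xt, yt)

    @property
    def n(self) -> int:
        return self.x_tables[0].shape[0] - 1 if self.x_tables else 0

    @property
    def m(self) -> int:
        return self.y_tables[0].shape[0] - 1 if self.y_tables else 0


def block_emission_log(x_iv, y_iv, tables: SubstringProbTable) -> float:
    """log Pr(x, y | R): prior-weighted sum over motifs of the factorized
    substring probabilities."""
    a1, a2 = x_iv
    b1, b2 = y_iv
    if not (0 <= a1 <= a2 <= tables.n and 0 <= b1 <= b2 <= tables.m):
        raise InputError("block interval outside the substring tables")
    vals = [tables.log_priors[i] + tables.x_tables[i][a1, a2]
            + tables.y_tables[i][b1, b2] for i in range(len(tables.x_tables))]
    if not vals:
        return NEG_INF
    vmax = max(vals)
    if vmax == NEG_INF:
        return NEG_INF
    return vmax + np.log(sum(np.exp(v - vmax) for v in vals))


def block_emission(x_iv, y_iv, library, tables: SubstringProbTable) -> float:
    """Block emission probability (linear space); ``library`` is accepted for
    interface symmetry but the priors already live in ``tables``."""
    return float(np.exp(block_emission_log(x_iv, y_iv, tables)))


# ------------------------------------------------------------- candidates
@dataclass
class CandidateBlockSet:
    """Interval pairs the generalized repeat state may emit.

    Either side may be empty (an interval [a, a)); never both.
    """

    a1: np.ndarray
    a2: np.ndarray
    b1: np.ndarray
    b2: np.ndarray

    def __len__(self) -> int:
        return len(self.a1)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[tuple[int, int], tuple[int, int]]]
                   ) -> "CandidateBlockSet":
        pairs = sorted(set((tuple(x), tuple(y)) for x, y in pairs))
        for (xa, xb), (ya, yb) in pairs:
            if xa == xb and ya == yb:
                raise InputError("candidate block with both sides empty")
        a1 = np.array([p[0][0] for p in pairs], dtype=np.int64)
        a2 = np.array([p[0][1] for p in pairs], dtype=np.int64)
        b1 = np.array([p[1][0] for p in pairs], dtype=np.int64)
        b2 = np.array([p[1][1] for p in pairs], dtype=np.int64)
        return cls(a1, a2, b1, b2)

    @classmethod
    def unrestricted(cls, n: int, m: int) -> "CandidateBlockSet":
        """Every interval pair (small instances only: O(n^2 m^2) members)."""
        pairs = []
        for xa in range(n + 1):
            for xb in range(xa, n + 1):
                for ya in range(m + 1):
                    for yb in range(ya, m + 1):
                        if xa == xb and ya == yb:
                            continue
                        pairs.append(((xa, xb), (ya, yb)))
        return cls.from_pairs(pairs)


def _endpoint_variants(v: int, tol: int, lo: int, hi: int) -> range:
    # a tol-wide window of candidate positions around an annotated endpoint
    if tol <= 0:
        return range(max(lo, min(v, hi)), min(hi, max(v, lo)) + 1)
    start = v - tol // 2
    return range(max(lo, start), min(hi, start + tol - 1) + 1)


def candidate_blocks(t_x: Sequence[tuple[int, int]],
                     t_y: Sequence[tuple[int, int]],
                     n: int, m: int, tol: int = 10) -> CandidateBlockSet:
    """Candidate repeat blocks from annotated interval sets.

    Each side of a candidate is either empty (at any position) or an
    interval whose endpoints both lie within a ``tol``-wide window of the
    endpoints of some annotated interval, so the number of candidates is
    bounded by (tol^2 |T_X| + n)(tol^2 |T_Y| + m).
    """
    def side(ivs, size):
        choices = {(a, a) for a in range(size + 1)}
        for (a, b) in ivs:
            for a_ in _endpoint_variants(a, tol, 0, size):
                for b_ in _endpoint_variants(b, tol, 0, size):
                    if a_ < b_:
                        choices.add((a_, b_))
        return sorted(choices)

    xs = side(t_x, n)
    ys = side(t_y, m)
    pairs = [(xi, yi) for xi in xs for yi in ys
             if not (xi[0] == xi[1] and yi[0] == yi[1])]
    return CandidateBlockSet.from_pairs(pairs)


# ------------------------------------------------------------ block model
@dataclass
class _BlockParams:
    """Scalar log-transitions of the generalized block model."""

    h2m: float
    h2x: float
    h2y: float
    h2e: float
    x2m: float
    x2x: float
    x2e: float
    y2m: float
    y2y: float
    y2e: float
    leta: float


def _block_params(sff: SffModel) -> _BlockParams:
    ts = sff.three_state
    eta = sff.eta
    with np.errstate(divide="ignore"):
        lg = lambda v: float(np.log(v)) if v > 0 else NEG_INF
        mrow = ts.m_row
        xrow = ts.i_row("IX")
        yrow = ts.i_row("IY")
        return _BlockParams(
            h2m=lg((1 - eta) * mrow["M"]), h2x=lg((1 - eta) * mrow["IX"]),
            h2y=lg((1 - eta) * mrow["IY"]), h2e=lg((1 - eta) * mrow["end"]),
            x2m=lg(xrow["M"]), x2x=lg(xrow["IX"]), x2e=lg(xrow["end"]),
            y2m=lg(yrow["M"]), y2y=lg(yrow["IY"]), y2e=lg(yrow["end"]),
            leta=lg(eta))


def _emission_grids(sff: SffModel, x: np.ndarray, y: np.ndarray):
    with np.errstate(divide="ignore"):
        lm = np.log(sff.three_state.match_emission)
        lbg = np.log(sff.three_state.background)
    n, m = len(x), len(y)
    em_m = np.full((n + 1, m + 1), NEG_INF)
    if n and m:
        em_m[1:, 1:] = lm[np.ix_(x, y)]
    em_x = np.full(n + 1, NEG_INF)
    em_x[1:] = lbg[x]
    em_y = np.full(m + 1, NEG_INF)
    em_y[1:] = lbg[y]
    return em_m, em_x, em_y


def _csr(cells, perm, ncells):
    ptr = np.zeros(ncells + 1, dtype=np.int64)
    for c in cells[perm]:
        ptr[c + 1] += 1
    return np.cumsum(ptr), perm


@njit(cache=True)
def _block_forward_kernel(n, m, em_m, em_x, em_y,
                          h2m, h2x, h2y, h2e, x2m, x2x, x2e,
                          y2m, y2y, y2e, leta,
                          end_ptr, end_idx, ba1, bb1, blem):
    A = np.full((n + 1, m + 1), NEG_INF)
    FM = np.full((n + 1, m + 1), NEG_INF)
    FX = np.full((n + 1, m + 1), NEG_INF)
    FY = np.full((n + 1, m + 1), NEG_INF)
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                fm = em_m[i, j] + np.logaddexp(
                    np.logaddexp(A[i - 1, j - 1] + h2m,
                                 FX[i - 1, j - 1] + x2m),
                    FY[i - 1, j - 1] + y2m)
            else:
                fm = NEG_INF
            FM[i, j] = fm
            if i > 0:
                FX[i, j] = em_x[i] + np.logaddexp(
                    A[i - 1, j] + h2x, FX[i - 1, j] + x2x)
            if j > 0:
                FY[i, j] = em_y[j] + np.logaddexp(
                    A[i, j - 1] + h2y, FY[i, j - 1] + y2y)
            acc = fm
            c = i * (m + 1) + j
            for e in range(end_ptr[c], end_ptr[c + 1]):
                b = end_idx[e]
                v = A[ba1[b], bb1[b]] + leta + blem[b]
                acc = np.logaddexp(acc, v)
            if i == 0 and j == 0:
                acc = np.logaddexp(acc, 0.0)
            A[i, j] = acc
    logZ = np.logaddexp(np.logaddexp(A[n, m] + h2e, FX[n, m] + x2e),
                        FY[n, m] + y2e)
    return A, FM, FX, FY, logZ


@njit(cache=True)
def _block_backward_kernel(n, m, em_m, em_x, em_y,
                           h2m, h2x, h2y, h2e, x2m, x2x, x2e,
                           y2m, y2y, y2e, leta,
                           st_ptr, st_idx, ba2, bb2, blem):
    BA = np.full((n + 1, m + 1), NEG_INF)
    BX = np.full((n + 1, m + 1), NEG_INF)
    BY = np.full((n + 1, m + 1), NEG_INF)
    for i in range(n, -1, -1):
        for j in range(m, -1, -1):
            accx = NEG_INF
            accy = NEG_INF
            acc = NEG_INF
            if i < n and j < m:
                vm = em_m[i + 1, j + 1] + BA[i + 1, j + 1]
                acc = np.logaddexp(acc, h2m + vm)
                accx = np.logaddexp(accx, x2m + vm)
                accy = np.logaddexp(accy, y2m + vm)
            if i < n:
                vx = em_x[i + 1] + BX[i + 1, j]
                acc = np.logaddexp(acc, h2x + vx)
                accx = np.logaddexp(accx, x2x + vx)
            if j < m:
                vy = em_y[j + 1] + BY[i, j + 1]
                acc = np.logaddexp(acc, h2y + vy)
                accy = np.logaddexp(accy, y2y + vy)
            if i == n and j == m:
                acc = np.logaddexp(acc, h2e)
                accx = np.logaddexp(accx, x2e)
                accy = np.logaddexp(accy, y2e)
            c = i * (m + 1) + j
            for e in range(st_ptr[c], st_ptr[c + 1]):
                b = st_idx[e]
                v = leta + blem[b] + BA[ba2[b], bb2[b]]
                acc = np.logaddexp(acc, v)
            BA[i, j] = acc
            BX[i, j] = accx
            BY[i, j] = accy
    return BA, BX, BY


@njit(cache=True)
def _block_gain_kernel(n, m, gm, gx, gy, end_ptr, end_idx, ba1, bb1, bgain):
    """Maximum-gain tiling: columns (match/X-gap/Y-gap, label 0) and
    candidate repeat blocks. Returns the DP value plus traceback codes:
    choice[i,j] = 0 match, 1 X-gap, 2 Y-gap, 3+b block index b, -1 none."""
    G = np.full((n + 1, m + 1), NEG_INF)
    choice = np.full((n + 1, m + 1), np.int64(-1))
    G[0, 0] = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            best = NEG_INF
            pick = np.int64(-1)
            if i > 0 and j > 0 and G[i - 1, j - 1] > NEG_INF:
                v = G[i - 1, j - 1] + gm[i, j]
                if v > best:
                    best = v
                    pick = 0
            if i > 0 and G[i - 1, j] > NEG_INF:
                v = G[i - 1, j] + gx[i, j]
                if v > best:
                    best = v
                    pick = 1
            if j > 0 and G[i, j - 1] > NEG_INF:
                v = G[i, j - 1] + gy[i, j]
                if v > best:
                    best = v
                    pick = 2
            c = i * (m + 1) + j
            for e in range(end_ptr[c], end_ptr[c + 1]):
                b = end_idx[e]
                if G[ba1[b], bb1[b]] > NEG_INF:
                    v = G[ba1[b], bb1[b]] + bgain[b]
                    if v > best:
                        best = v
                        pick = 3 + b
            G[i, j] = best
            choice[i, j] = pick
    return G[n, m], choice


@njit(cache=True)
def _block_viterbi_kernel(n, m, em_m, em_x, em_y,
                          h2m, h2x, h2y, h2e, x2m, x2x, x2e,
                          y2m, y2y, y2e, leta,
                          end_ptr, end_idx, ba1, bb1, blem):
    """Generalized-HMM Viterbi over the block model.

    bpA codes: 0/1/2 = match column arriving from hub/X/Y context at
    (i-1, j-1); 3+b = block b; -1 unset. bpX/bpY: 0 = from hub, 1/2 = gap
    extension."""
    VA = np.full((n + 1, m + 1), NEG_INF)
    VX = np.full((n + 1, m + 1), NEG_INF)
    VY = np.full((n + 1, m + 1), NEG_INF)
    bpA = np.full((n + 1, m + 1), np.int64(-1))
    bpX = np.full((n + 1, m + 1), np.int64(-1))
    bpY = np.full((n + 1, m + 1), np.int64(-1))
    for i in range(n + 1):
        for j in range(m + 1):
            best = NEG_INF
            pick = np.int64(-1)
            if i == 0 and j == 0:
                best = 0.0
                pick = -2  # origin
            if i > 0 and j > 0:
                e = em_m[i, j]
                v = VA[i - 1, j - 1] + h2m + e
                if v > best:
                    best = v
                    pick = 0
                v = VX[i - 1, j - 1] + x2m + e
                if v > best:
                    best = v
                    pick = 1
                v = VY[i - 1, j - 1] + y2m + e
                if v > best:
                    best = v
                    pick = 2
            c = i * (m + 1) + j
            for e0 in range(end_ptr[c], end_ptr[c + 1]):
                b = end_idx[e0]
                v = VA[ba1[b], bb1[b]] + leta + blem[b]
                if v > best:
                    best = v
                    pick = 3 + b
            VA[i, j] = best
            bpA[i, j] = pick
            if i > 0:
                e = em_x[i]
                v1 = VA[i - 1, j] + h2x + e
                v2 = VX[i - 1, j] + x2x + e
                if v1 >= v2:
                    VX[i, j] = v1
                    bpX[i, j] = 0
                else:
                    VX[i, j] = v2
                    bpX[i, j] = 1
            if j > 0:
                e = em_y[j]
                v1 = VA[i, j - 1] + h2y + e
                v2 = VY[i, j - 1] + y2y + e
                if v1 >= v2:
                    VY[i, j] = v1
                    bpY[i, j] = 0
                else:
                    VY[i, j] = v2
                    bpY[i, j] = 2
    s0 = VA[n, m] + h2e
    s1 = VX[n, m] + x2e
    s2 = VY[n, m] + y2e
    if s0 >= s1 and s0 >= s2:
        return s0, 0, VA, VX, VY, bpA, bpX, bpY
    if s1 >= s2:
        return s1, 1, VA, VX, VY, bpA, bpX, bpY
    return s2, 2, VA, VX, VY, bpA, bpX, bpY


# --------------------------------------------------------------- decoding
@dataclass
class BlockDecodeResult:
    alignment: Alignment
    annotation: RepeatAnnotation
    blocks: list[Block]
    score: float                     # total gain or structure log-probability
    log_total: float | None = None   # block-model total probability


def _prepare_blocks(sff: SffModel, X, Y, candidates, tables):
    x = encode(X) if not isinstance(X, np.ndarray) else X
    y = encode(Y) if not isinstance(Y, np.ndarray) else Y
    n, m = len(x), len(y)
    if candidates is None:
        candidates = CandidateBlockSet.unrestricted(n, m)
    if tables is None:
        tables = SubstringProbTable.build(sff, x, y)
    k = len(sff.library)
    nb = len(candidates)
    if nb and k:
        stack = np.empty((k, nb))
        for i in range(k):
            stack[i] = (tables.log_priors[i]
                        + tables.x_tables[i][candidates.a1, candidates.a2]
                        + tables.y_tables[i][candidates.b1, candidates.b2])
        with np.errstate(divide="ignore"):
            blem = logsumexp(stack, axis=0)
    else:
        blem = np.full(nb, NEG_INF)
    params = _block_params(sff)
    em = _emission_grids(sff, x, y)
    ncells = (n + 1) * (m + 1)
    end_cells = candidates.a2 * (m + 1) + candidates.b2
    # deterministic tie-breaking: blocks visited by (start x, start y)
    end_perm = np.lexsort((candidates.b1, candidates.a1, end_cells))
    end_ptr, _ = _csr(end_cells, end_perm, ncells)
    st_cells = candidates.a1 * (m + 1) + candidates.b1
    st_perm = np.lexsort((candidates.b2, candidates.a2, st_cells))
    st_ptr, _ = _csr(st_cells, st_perm, ncells)
    grouping = dict(end_ptr=end_ptr, end_idx=end_perm,
                    st_ptr=st_ptr, st_idx=st_perm)
    return x, y, n, m, candidates, tables, blem, params, em, grouping


def block_model_total(sff: SffModel, X, Y, candidates=None, tables=None) -> float:
    """Total log-probability of the block model (equals the SFF total when
    candidates are unrestricted)."""
    x, y, n, m, cand, tables, blem, p, em, grp = _prepare_blocks(
        sff, X, Y, candidates, tables)
    _, _, _, _, logZ = _block_forward_kernel(
        n, m, em[0], em[1], em[2], p.h2m, p.h2x, p.h2y, p.h2e,
        p.x2m, p.x2x, p.x2e, p.y2m, p.y2y, p.y2e, p.leta,
        grp["end_ptr"], grp["end_idx"], cand.a1, cand.b1, blem)
    return float(logZ)


def block_decode(sff: SffModel, X, Y, candidates=None,
                 tables=None) -> BlockDecodeResult:
    """Maximum-expected-gain tiling of repeat blocks and single columns."""
    x, y, n, m, cand, tables, blem, p, em, grp = _prepare_blocks(
        sff, X, Y, candidates, tables)
    A, FM, FX, FY, logZ = _block_forward_kernel(
        n, m, em[0], em[1], em[2], p.h2m, p.h2x, p.h2y, p.h2e,
        p.x2m, p.x2x, p.x2e, p.y2m, p.y2y, p.y2e, p.leta,
        grp["end_ptr"], grp["end_idx"], cand.a1, cand.b1, blem)
    if logZ == NEG_INF:
        raise ZeroProbabilityError("block model assigns zero probability")
    BA, BX, BY = _block_backward_kernel(
        n, m, em[0], em[1], em[2], p.h2m, p.h2x, p.h2y, p.h2e,
        p.x2m, p.x2x, p.x2e, p.y2m, p.y2y, p.y2e, p.leta,
        grp["st_ptr"], grp["st_idx"], cand.a2, cand.b2, blem)
    # label-0 column gains (posteriors in the block model); a match state
    # hands over to the hub with probability one, so its backward value is BA
    gm = np.exp(FM + BA - logZ)
    gx = np.exp(FX + BX - logZ)
    gy = np.exp(FY + BY - logZ)
    # block gains: posterior * number of non-gap symbols
    post = np.exp(A[cand.a1, cand.b1] + p.leta + blem
                  + BA[cand.a2, cand.b2] - logZ)
    size = (cand.a2 - cand.a1) + (cand.b2 - cand.b1)
    bgain = post * size
    total, choice = _block_gain_kernel(
        n, m, gm, gx, gy, grp["end_ptr"], grp["end_idx"],
        cand.a1, cand.b1, bgain)
    aln, ann, blocks = _traceback_tiling(choice, cand, n, m)
    return BlockDecodeResult(aln, ann, blocks, float(total),
                             log_total=float(logZ))


def _traceback_tiling(choice, cand, n, m):
    moves_r: list[int] = []
    labels_r: list[int] = []
    blocks: list[Block] = []
    i, j = n, m
    while i > 0 or j > 0:
        k = choice[i, j]
        if k < 0:
            raise ModelError("block traceback failed")
        if k >= 3:
            b = k - 3
            a1, a2 = int(cand.a1[b]), int(cand.a2[b])
            b1, b2 = int(cand.b1[b]), int(cand.b2[b])
            blocks.append(Block((a1, a2), (b1, b2), 1))
            moves_r.extend([YGAP] * (b2 - b1))
            moves_r.extend([XGAP] * (a2 - a1))
            labels_r.extend([1] * ((a2 - a1) + (b2 - b1)))
            i, j = a1, b1
        else:
            moves_r.append(int(k))
            labels_r.append(0)
            if k == MATCH:
                i, j = i - 1, j - 1
            elif k == XGAP:
                i -= 1
            else:
                j -= 1
    moves_r.reverse()
    labels_r.reverse()
    blocks.reverse()
    return Alignment(moves_r), RepeatAnnotation(labels_r), blocks


def block_viterbi(sff: SffModel, X, Y, candidates=None,
                  tables=None) -> BlockDecodeResult:
    """Most probable block structure (generalized-HMM Viterbi)."""
    x, y, n, m, cand, tables, blem, p, em, grp = _prepare_blocks(
        sff, X, Y, candidates, tables)
    score, layer, VA, VX, VY, bpA, bpX, bpY = _block_viterbi_kernel(
        n, m, em[0], em[1], em[2], p.h2m, p.h2x, p.h2y, p.h2e,
        p.x2m, p.x2x, p.x2e, p.y2m, p.y2y, p.y2e, p.leta,
        grp["end_ptr"], grp["end_idx"], cand.a1, cand.b1, blem)
    if score == NEG_INF:
        raise ZeroProbabilityError("block model admits no structure")
    moves_r: list[int] = []
    labels_r: list[int] = []
    blocks: list[Block] = []
    i, j = n, m
    while True:
        if layer == 0:
            if i == 0 and j == 0 and bpA[i, j] == -2:
                break
            k = bpA[i, j]
            if k == -2:
                break
            if k < 0:
                raise ModelError("block Viterbi traceback failed")
            if k >= 3:
                b = k - 3
                a1, a2 = int(cand.a1[b]), int(cand.a2[b])
                b1, b2 = int(cand.b1[b]), int(cand.b2[b])
                blocks.append(Block((a1, a2), (b1, b2), 1))
                moves_r.extend([YGAP] * (b2 - b1))
                moves_r.extend([XGAP] * (a2 - a1))
                labels_r.extend([1] * ((a2 - a1) + (b2 - b1)))
                i, j = a1, b1
            else:
                moves_r.append(MATCH)
                labels_r.append(0)
                layer = k
                i, j = i - 1, j - 1
        elif layer == 1:
            k = bpX[i, j]
            if k < 0:
                raise ModelError("block Viterbi traceback failed")
            moves_r.append(XGAP)
            labels_r.append(0)
            layer = 0 if k == 0 else 1
            i -= 1
        else:
            k = bpY[i, j]
            if k < 0:
                raise ModelError("block Viterbi traceback failed")
            moves_r.append(YGAP)
            labels_r.append(0)
            layer = 0 if k == 0 else 2
            j -= 1
    moves_r.reverse()
    labels_r.reverse()
    blocks.reverse()
    return BlockDecodeResult(Alignment(moves_r), RepeatAnnotation(labels_r),
                             blocks, float(score))
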