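"""Compiled lattice recursions for pair HMMs.

The public :class:`~sffalign.hmm.PairHMM` keeps a dict-based, name-addressed
representation; this module flattens it to arrays once per model and runs the
dynamic programming with numba. All arithmetic is in natural-log space with
``-inf`` marking impossible configurations.

Lattice convention: cell (i, j) means i symbols of X and j symbols of Y have
been consumed, i in 0..n, j in 0..m. States generating both symbols advance
from (i-1, j-1), X-only states from (i-1, j), Y-only states from (i, j-1) and
silent states stay within the cell (processed in a topological order of the
silent subgraph). A state with context order k > 0 emits conditionally on the
symbol k positions earlier in its own sequence; when that symbol does not
exist the emission falls back to a dedicated background row.

Lattices are stored as (i, j, state) so that one cell's state vector is
contiguous; the public wrappers transpose to (state, i, j) where needed.
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit

CLS_BOTH = 0
CLS_X = 1
CLS_Y = 2
CLS_SILENT = 3

NEG_INF = float("-inf")


@njit(cache=True, inline="always")
def _lse_add(acc, v):
    # acc := log(exp(acc) + exp(v)), skipping work for negligible terms
    if v == NEG_INF:
        return acc
    if v > acc:
        acc, v = v, acc
    d = v - acc
    if d > -37.0:
        return acc + math.log1p(math.exp(d))
    return acc


@njit(cache=True)
def _ctx_index(seq, pos0, k):
    # pos0: 0-based index of the symbol being emitted; row 4 = no context.
    if k == 0:
        return 0
    idx = pos0 - k
    if idx < 0:
        return 4
    return seq[idx]


@njit(cache=True)
def forward_kernel(cls, ctxk, le_pair, le_single, proc,
                   tin_ptr, tin_src, tin_logp, start, x, y, allowed):
    ns = cls.shape[0]
    n = x.shape[0]
    m = y.shape[0]
    F = np.full((n + 1, m + 1, ns), NEG_INF)
    if allowed[0, 0]:
        F[0, 0, start] = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            if not allowed[i, j]:
                continue
            cur = F[i, j]
            for p in range(proc.shape[0]):
                s = proc[p]
                c = cls[s]
                if c == CLS_SILENT:
                    acc = NEG_INF
                    for e in range(tin_ptr[s], tin_ptr[s + 1]):
                        acc = _lse_add(acc, cur[tin_src[e]] + tin_logp[e])
                    cur[s] = acc
                else:
                    if c == CLS_BOTH:
                        if i == 0 or j == 0:
                            continue
                        pi = i - 1
                        pj = j - 1
                        em = le_pair[s, x[i - 1], y[j - 1]]
                    elif c == CLS_X:
                        if i == 0:
                            continue
                        pi = i - 1
                        pj = j
                        em = le_single[s, _ctx_index(x, i - 1, ctxk[s]), x[i - 1]]
                    else:
                        if j == 0:
                            continue
                        pi = i
                        pj = j - 1
                        em = le_single[s, _ctx_index(y, j - 1, ctxk[s]), y[j - 1]]
                    if not allowed[pi, pj] or em == NEG_INF:
                        continue
                    prev = F[pi, pj]
                    acc = NEG_INF
                    for e in range(tin_ptr[s], tin_ptr[s + 1]):
                        acc = _lse_add(acc, prev[tin_src[e]] + tin_logp[e])
                    cur[s] = acc + em
    return F


@njit(cache=True)
def backward_kernel(cls, ctxk, le_pair, le_single, proc,
                    out_ptr, out_dst, out_logp, end, x, y, allowed):
    ns = cls.shape[0]
    n = x.shape[0]
    m = y.shape[0]
    B = np.full((n + 1, m + 1, ns), NEG_INF)
    if allowed[n, m]:
        B[n, m, end] = 0.0
    vcache = np.empty(ns)
    for i in range(n, -1, -1):
        for j in range(m, -1, -1):
            if not allowed[i, j]:
                continue
            cur = B[i, j]
            # successor value of each emitting state, computed once per cell
            for t in range(ns):
                c = cls[t]
                if c == CLS_SILENT:
                    continue
                if c == CLS_BOTH:
                    if i == n or j == m or not allowed[i + 1, j + 1]:
                        vcache[t] = NEG_INF
                    else:
                        vcache[t] = B[i + 1, j + 1, t] + le_pair[t, x[i], y[j]]
                elif c == CLS_X:
                    if i == n or not allowed[i + 1, j]:
                        vcache[t] = NEG_INF
                    else:
                        vcache[t] = B[i + 1, j, t] + le_single[
                            t, _ctx_index(x, i, ctxk[t]), x[i]]
                else:
                    if j == m or not allowed[i, j + 1]:
                        vcache[t] = NEG_INF
                    else:
                        vcache[t] = B[i, j + 1, t] + le_single[
                            t, _ctx_index(y, j, ctxk[t]), y[j]]
            for p in range(proc.shape[0]):
                s = proc[p]
                if s == end and i == n and j == m:
                    continue
                acc = NEG_INF
                for e in range(out_ptr[s], out_ptr[s + 1]):
                    t = out_dst[e]
                    if cls[t] == CLS_SILENT:
                        v = cur[t]
                    else:
                        v = vcache[t]
                    acc = _lse_add(acc, v + out_logp[e])
                cur[s] = acc
    return B


@njit(cache=True)
def chain_kernel(gm, gx, gy):
    """Maximum-gain chain of compatible alignment columns.

    gm[i, j]: gain of match column (x_i, y_j); gx[i, j]: gain of the X-gap
    column placing x_i after y_j; gy[i, j]: Y-gap column. Ties prefer
    match > X-gap > Y-gap. Returns (total gain, moves) where moves[i, j]
    encodes the incoming column kind (0 match, 1 X-gap, 2 Y-gap, -1 none).
    """
    n = gm.shape[0] - 1
    m = gm.shape[1] - 1
    G = np.full((n + 1, m + 1), NEG_INF)
    mv = np.full((n + 1, m + 1), -1, dtype=np.int8)
    G[0, 0] = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            best = NEG_INF
            bmv = -1
            if i > 0 and j > 0 and G[i - 1, j - 1] > NEG_INF:
                v = G[i - 1, j - 1] + gm[i, j]
                if v > best:
                    best = v
                    bmv = 0
            if i > 0 and G[i - 1, j] > NEG_INF:
                v = G[i - 1, j] + gx[i, j]
                if v > best:
                    best = v
                    bmv = 1
            if j > 0 and G[i, j - 1] > NEG_INF:
                v = G[i, j - 1] + gy[i, j]
                if v > best:
                    best = v
                    bmv = 2
            G[i, j] = best
            mv[i, j] = bmv
    return G[n, m], mv


@njit(cache=True)
def substring_forward_kernel(cls, ctxk, le_single, proc,
                             tin_ptr, tin_src, tin_logp, start, end, seq):
    """All-substrings forward for a single-sequence fragment.

    States are X-only or silent. Entry [a, b] of the returned table is the
    log-probability that one entry-to-exit pass emits exactly seq[a:b);
    context orders are resolved within the substring. One forward sweep is
    run per start position.
    """
    ns = cls.shape[0]
    n = seq.shape[0]
    table = np.full((n + 1, n + 1), NEG_INF)
    F = np.full((n - 0 + 1, ns), NEG_INF)
    for a in range(n + 1):
        L = n - a
        for i in range(L + 1):
            for s in range(ns):
                F[i, s] = NEG_INF
        F[0, start] = 0.0
        for i in range(L + 1):
            cur = F[i]
            for p in range(proc.shape[0]):
                s = proc[p]
                if cls[s] == CLS_SILENT:
                    acc = NEG_INF
                    for e in range(tin_ptr[s], tin_ptr[s + 1]):
                        acc = _lse_add(acc, cur[tin_src[e]] + tin_logp[e])
                    cur[s] = acc
                else:
                    if i == 0:
                        continue
                    k = ctxk[s]
                    if k == 0:
                        ctx = 0
                    elif i - 1 - k >= 0:
                        ctx = seq[a + i - 1 - k]
                    else:
                        ctx = 4
                    em = le_single[s, ctx, seq[a + i - 1]]
                    if em == NEG_INF:
                        continue
                    prev = F[i - 1]
                    acc = NEG_INF
                    for e in range(tin_ptr[s], tin_ptr[s + 1]):
                        acc = _lse_add(acc, prev[tin_src[e]] + tin_logp[e])
                    cur[s] = acc + em
            table[a, a + i] = cur[end]
    return table


@njit(cache=True)
def backward_rows_kernel(cls, ctxk, le_pair, le_single, proc,
                         out_ptr, out_dst, out_logp, end, x, y, allowed,
                         hi, lo, row_above, has_above):
    """Backward values for lattice rows hi..lo only.

    ``row_above`` must hold B[hi+1] (shape (m+1, ns)) unless hi == n.
    Returns the block as (hi-lo+1, m+1, ns) with ascending row index.
    Used by the checkpointed posterior pipeline to keep memory at
    O(sqrt(n)) rows instead of the full lattice.
    """
    ns = cls.shape[0]
    n = x.shape[0]
    m = y.shape[0]
    out = np.full((hi - lo + 1, m + 1, ns), NEG_INF)
    vcache = np.empty(ns)
    for i in range(hi, lo - 1, -1):
        bi = i - lo
        if i == n and allowed[n, m]:
            out[bi, m, end] = 0.0
        for j in range(m, -1, -1):
            if not allowed[i, j]:
                continue
            cur = out[bi, j]
            for t in range(ns):
                c = cls[t]
                if c == CLS_SILENT:
                    continue
                if c == CLS_BOTH:
                    if i == n or j == m or not allowed[i + 1, j + 1]:
                        vcache[t] = NEG_INF
                    else:
                        above = out[bi + 1] if i < hi else row_above
                        vcache[t] = above[j + 1, t] + le_pair[t, x[i], y[j]]
                elif c == CLS_X:
                    if i == n or not allowed[i + 1, j]:
                        vcache[t] = NEG_INF
                    else:
                        above = out[bi + 1] if i < hi else row_above
                        vcache[t] = above[j, t] + le_single[
                            t, _ctx_index(x, i, ctxk[t]), x[i]]
                else:
                    if j == m or not allowed[i, j + 1]:
                        vcache[t] = NEG_INF
                    else:
                        vcache[t] = out[bi, j + 1, t] + le_single[
                            t, _ctx_index(y, j, ctxk[t]), y[j]]
            for p in range(proc.shape[0]):
                s = proc[p]
                if s == end and i == n and j == m:
                    continue
                acc = NEG_INF
                for e in range(out_ptr[s], out_ptr[s + 1]):
                    t = out_dst[e]
                    if cls[t] == CLS_SILENT:
                        v = cur[t]
                    else:
                        v = vcache[t]
                    acc = _lse_add(acc, v + out_logp[e])
                cur[s] = acc
    return out


@njit(cache=True)
def grouped_forward_rows_kernel(cls, ctxk, le_pair, le_single, proc,
                                tin_ptr, tin_src, tin_logp, start,
                                gid, Bblock, log_total, x, y, allowed,
                                lo, hi, Fprev, P):
    """Streamed forward over rows lo..hi, accumulating grouped posteriors.

    ``Fprev`` carries the forward row lo-1 between calls (row hi is left in
    it on return); ``Bblock`` holds backward rows lo..hi.
    """
    ns = cls.shape[0]
    n = x.shape[0]
    m = y.shape[0]
    Fcur = np.full((m + 1, ns), NEG_INF)
    for i in range(lo, hi + 1):
        for j in range(m + 1):
            for s in range(ns):
                Fcur[j, s] = NEG_INF
        brows = Bblock[i - lo]
        for j in range(m + 1):
            if not allowed[i, j]:
                continue
            if i == 0 and j == 0:
                Fcur[0, start] = 0.0
            cur = Fcur[j]
            brow = brows[j]
            for p in range(proc.shape[0]):
                s = proc[p]
                c = cls[s]
                if c == CLS_SILENT:
                    acc = NEG_INF
                    for e in range(tin_ptr[s], tin_ptr[s + 1]):
                        acc = _lse_add(acc, cur[tin_src[e]] + tin_logp[e])
                    cur[s] = acc
                    continue
                if c == CLS_BOTH:
                    if i == 0 or j == 0:
                        continue
                    prev = Fprev[j - 1]
                    em = le_pair[s, x[i - 1], y[j - 1]]
                elif c == CLS_X:
                    if i == 0:
                        continue
                    prev = Fprev[j]
                    em = le_single[s, _ctx_index(x, i - 1, ctxk[s]), x[i - 1]]
                else:
                    if j == 0:
                        continue
                    prev = Fcur[j - 1]
                    em = le_single[s, _ctx_index(y, j - 1, ctxk[s]), y[j - 1]]
                if em == NEG_INF:
                    continue
                acc = NEG_INF
                for e in range(tin_ptr[s], tin_ptr[s + 1]):
                    acc = _lse_add(acc, prev[tin_src[e]] + tin_logp[e])
                f = acc + em
                cur[s] = f
                g = gid[s]
                if g >= 0 and f > NEG_INF:
                    b = brow[s]
                    if b > NEG_INF:
                        P[g, i, j] += math.exp(f + b - log_total)
        for j in range(m + 1):
            for s in range(ns):
                Fprev[j, s] = Fcur[j, s]
    return P


@njit(cache=True)
def viterbi_lowmem_kernel(cls, ctxk, le_pair, le_single, proc,
                          tin_ptr, tin_src, tin_logp, start, x, y, allowed):
    """Viterbi with rolling value rows and a full int16 backpointer table.

    bp[i, j, s] stores the index of the chosen incoming edge *within* state
    s's in-edge list (tin_ptr[s] + bp gives the global edge), or -1.
    Returns (final log-probability at the end state, bp).
    """
    ns = cls.shape[0]
    n = x.shape[0]
    m = y.shape[0]
    Vprev = np.full((m + 1, ns), NEG_INF)
    Vcur = np.full((m + 1, ns), NEG_INF)
    bp = np.full((n + 1, m + 1, ns), -1, dtype=np.int16)
    final = NEG_INF
    for i in range(n + 1):
        if i > 0:
            tmp = Vprev
            Vprev = Vcur
            Vcur = tmp
            for j in range(m + 1):
                for s in range(ns):
                    Vcur[j, s] = NEG_INF
        for j in range(m + 1):
            if not allowed[i, j]:
                continue
            if i == 0 and j == 0:
                Vcur[0, start] = 0.0
            cur = Vcur[j]
            for p in range(proc.shape[0]):
                s = proc[p]
                c = cls[s]
                if c == CLS_SILENT:
                    prev = cur
                    em = 0.0
                else:
                    if c == CLS_BOTH:
                        if i == 0 or j == 0:
                            continue
                        pi = i - 1
                        pj = j - 1
                        em = le_pair[s, x[i - 1], y[j - 1]]
                        if pi >= 0 and not allowed[pi, pj]:
                            continue
                        prev = Vprev[pj]
                    elif c == CLS_X:
                        if i == 0:
                            continue
                        pi = i - 1
                        pj = j
                        em = le_single[s, _ctx_index(x, i - 1, ctxk[s]), x[i - 1]]
                        if not allowed[pi, pj]:
                            continue
                        prev = Vprev[pj]
                    else:
                        if j == 0:
                            continue
                        pi = i
                        pj = j - 1
                        em = le_single[s, _ctx_index(y, j - 1, ctxk[s]), y[j - 1]]
                        if not allowed[pi, pj]:
                            continue
                        prev = Vcur[pj]
                    if em == NEG_INF:
                        continue
                best = NEG_INF
                best_e = -1
                base = tin_ptr[s]
                for e in range(base, tin_ptr[s + 1]):
                    v = prev[tin_src[e]] + tin_logp[e]
                    if v > best:
                        best = v
                        best_e = e - base
                if best_e >= 0 and best > NEG_INF:
                    cur[s] = best + em
                    bp[i, j, s] = best_e
    return Vcur, bp
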