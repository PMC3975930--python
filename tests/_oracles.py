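"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive pure Python: probabilities are
aggregated by enumerating generating state paths (or block structures)
recursively, without any of the compiled dynamic programming the package
uses. Only feasible for tiny instances (n, m <= 3, small models).
"""
from __future__ import annotations

import itertools
import math
from collections import defaultdict

import numpy as np

from sffalign._alphabet import encode
from sffalign.hmm import EmissionClass, PairHMM

PRUNE = 1e-300


def _emission_prob(model, state, seq, pos0):
    """Probability of state emitting seq[pos0] given its context."""
    e = model.emissions[state]
    if e.ndim == 1:
        return e[seq[pos0]]
    k = model.context_order[state]
    ctx = seq[pos0 - k] if (k > 0 and pos0 - k >= 0) else 4
    if k == 0:
        ctx = 0
    return e[ctx, seq[pos0]]


def enum_paths(model: PairHMM, X: str, Y: str, max_depth: int = 120):
    """Yield (state_path, probability) over all complete generating paths."""
    x, y = encode(X), encode(Y)
    n, m = len(x), len(y)
    out = []

    def rec(s, i, j, p, path):
        if len(path) > max_depth or p < PRUNE:
            return
        for dst, tp in model.transitions.get(s, {}).items():
            q = p * tp
            if q == 0.0:
                continue
            if dst == model.end:
                if i == n and j == m:
                    out.append((list(path), q))
                continue
            cls = model.emission_class[dst]
            if cls == EmissionClass.SILENT:
                path.append(dst)
                rec(dst, i, j, q, path)
                path.pop()
            elif cls == EmissionClass.BOTH:
                if i < n and j < m:
                    e = model.emissions[dst][x[i], y[j]]
                    if e > 0:
                        path.append(dst)
                        rec(dst, i + 1, j + 1, q * e, path)
                        path.pop()
            elif cls == EmissionClass.X_ONLY:
                if i < n:
                    e = _emission_prob(model, dst, x, i)
                    if e > 0:
                        path.append(dst)
                        rec(dst, i + 1, j, q * e, path)
                        path.pop()
            else:
                if j < m:
                    e = _emission_prob(model, dst, y, j)
                    if e > 0:
                        path.append(dst)
                        rec(dst, i, j + 1, q * e, path)
                        path.pop()

    rec(model.start, 0, 0, 1.0, [])
    return out


def enum_total(model, X, Y) -> float:
    return sum(p for _, p in enum_paths(model, X, Y))


def enum_best_path(model, X, Y):
    paths = enum_paths(model, X, Y)
    if not paths:
        return [], 0.0
    return max(paths, key=lambda t: t[1])


def path_columns(model, path):
    """(kind, i, j, label) for every emitting state of a path."""
    cols = []
    i = j = 0
    for s in path:
        cls = model.emission_class[s]
        if cls == EmissionClass.SILENT:
            continue
        if cls == EmissionClass.BOTH:
            i += 1
            j += 1
            kind = 0
        elif cls == EmissionClass.X_ONLY:
            i += 1
            kind = 1
        else:
            j += 1
            kind = 2
        cols.append((kind, i, j, 1 if model.is_repeat_state(s) else 0))
    return cols


def enum_state_posteriors(model, X, Y):
    """dict (state, i, j) -> posterior that the state emits there."""
    paths = enum_paths(model, X, Y)
    total = sum(p for _, p in paths)
    acc = defaultdict(float)
    for path, p in paths:
        i = j = 0
        for s in path:
            cls = model.emission_class[s]
            if cls == EmissionClass.SILENT:
                continue
            if cls == EmissionClass.BOTH:
                i += 1
                j += 1
            elif cls == EmissionClass.X_ONLY:
                i += 1
            else:
                j += 1
            acc[(s, i, j)] += p
    return {k: v / total for k, v in acc.items()}, total


def enum_labeled_column_posteriors(model, X, Y):
    """dict (kind, i, j, label) -> posterior."""
    paths = enum_paths(model, X, Y)
    total = sum(p for _, p in paths)
    acc = defaultdict(float)
    for path, p in paths:
        for col in path_columns(model, path):
            acc[col] += p
    return {k: v / total for k, v in acc.items()}, total


def all_alignment_moves(n, m):
    """All monotone move sequences (0 match, 1 X-gap, 2 Y-gap) for (n, m)."""
    out = []

    def rec(i, j, moves):
        if i == n and j == m:
            out.append(list(moves))
            return
        if i < n and j < m:
            moves.append(0)
            rec(i + 1, j + 1, moves)
            moves.pop()
        if i < n:
            moves.append(1)
            rec(i + 1, j, moves)
            moves.pop()
        if j < m:
            moves.append(2)
            rec(i, j + 1, moves)
            moves.pop()

    rec(0, 0, [])
    return out


def best_alignment_gain(gain_of_column, n, m):
    """Exhaustive maximum over valid labeled alignments.

    ``gain_of_column(kind, i, j)`` must return the per-column gain already
    maximized over labels. Returns the best total gain.
    """
    best = -math.inf
    for moves in all_alignment_moves(n, m):
        i = j = 0
        g = 0.0
        for mv in moves:
            if mv != 2:
                i += 1
            if mv != 1:
                j += 1
            g += gain_of_column(mv, i, j)
        best = max(best, g)
    return best


# --------------------------------------------------------- block structures
def enum_fragment_emission(fragment, S: str) -> float:
    """Pr(fragment emits exactly S), by path enumeration."""
    return enum_total(fragment, S, "")


def enum_block_structures(sff, X, Y, candidates):
    """All block-model structures with probabilities.

    A structure is a tuple of items: ('M', i, j), ('X', i, j), ('Y', i, j)
    for single columns (positions after consuming) or
    ('R', a1, a2, b1, b2) for a repeat block. Block emissions are computed
    by fragment path enumeration; the three-state transitions follow the
    hub wiring of the SFF (repeats entered only from start/M/repeat-exit).
    """
    ts = sff.three_state
    eta = sff.eta
    mrow = ts.m_row
    xrow = ts.i_row("IX")
    yrow = ts.i_row("IY")
    x, y = encode(X), encode(Y)
    n, m = len(x), len(y)
    cand = [(int(a1), int(a2), int(b1), int(b2))
            for a1, a2, b1, b2 in zip(candidates.a1, candidates.a2,
                                      candidates.b1, candidates.b2)]
    bl_em = {}
    for a1, a2, b1, b2 in cand:
        em = 0.0
        for k, (motif, w) in enumerate(sff.library.motifs):
            em += w * enum_fragment_emission(sff.x_fragment(k), X[a1:a2]) * \
                enum_fragment_emission(sff.y_fragment(k), Y[b1:b2])
        bl_em[(a1, a2, b1, b2)] = em

    out = []

    def hub_options(i, j):
        # (item, next_state, prob); next_state in {'hub','X','Y',None=end}
        opts = []
        if i < n and j < m:
            opts.append((("M", i + 1, j + 1), "hub",
                         (1 - eta) * mrow["M"] * ts.match_emission[x[i], y[j]]))
        if i < n:
            opts.append((("X", i + 1, j), "X",
                         (1 - eta) * mrow["IX"] * ts.background[x[i]]))
        if j < m:
            opts.append((("Y", i, j + 1), "Y",
                         (1 - eta) * mrow["IY"] * ts.background[y[j]]))
        for (a1, a2, b1, b2) in cand:
            if a1 == i and b1 == j:
                opts.append((("R", a1, a2, b1, b2), "hub",
                             eta * bl_em[(a1, a2, b1, b2)]))
        return opts

    def rec(state, i, j, p, items):
        if p < PRUNE:
            return
        if state == "hub":
            if i == n and j == m:
                out.append((tuple(items), p * (1 - eta) * mrow["end"]))
            for item, nxt, q in hub_options(i, j):
                if q > 0:
                    items.append(item)
                    ni, nj = (item[1], item[2]) if item[0] != "R" else (item[2], item[4])
                    rec(nxt, ni, nj, p * q, items)
                    items.pop()
        elif state == "X":
            if i == n and j == m:
                out.append((tuple(items), p * xrow["end"]))
            if i < n and j < m:
                q = xrow["M"] * ts.match_emission[x[i], y[j]]
                items.append(("M", i + 1, j + 1))
                rec("hub", i + 1, j + 1, p * q, items)
                items.pop()
            if i < n:
                q = xrow["IX"] * ts.background[x[i]]
                items.append(("X", i + 1, j))
                rec("X", i + 1, j, p * q, items)
                items.pop()
        else:
            if i == n and j == m:
                out.append((tuple(items), p * yrow["end"]))
            if i < n and j < m:
                q = yrow["M"] * ts.match_emission[x[i], y[j]]
                items.append(("M", i + 1, j + 1))
                rec("hub", i + 1, j + 1, p * q, items)
                items.pop()
            if j < m:
                q = yrow["IY"] * ts.background[y[j]]
                items.append(("Y", i, j + 1))
                rec("Y", i, j + 1, p * q, items)
                items.pop()

    rec("hub", 0, 0, 1.0, [])
    return out


def block_structure_posteriors(structures):
    """Item posteriors (columns and blocks) from enumerated structures."""
    total = sum(p for _, p in structures)
    acc = defaultdict(float)
    for items, p in structures:
        for item in items:
            acc[item] += p
    return {k: v / total for k, v in acc.items()}, total


def enum_best_tiling(sff, X, Y, candidates):
    """Exhaustive optimum of the block-decoding gain."""
    structures = enum_block_structures(sff, X, Y, candidates)
    post, total = block_structure_posteriors(structures)
    n, m = len(X), len(Y)
    best = [-math.inf]

    def gain(item):
        p = post.get(item, 0.0)
        if item[0] == "R":
            _, a1, a2, b1, b2 = item
            return p * ((a2 - a1) + (b2 - b1))
        return p

    cand = [(int(a1), int(a2), int(b1), int(b2))
            for a1, a2, b1, b2 in zip(candidates.a1, candidates.a2,
                                      candidates.b1, candidates.b2)]

    def rec(i, j, g):
        if i == n and j == m:
            best[0] = max(best[0], g)
            # fall through: can still append empty-progress blocks? no:
            # blocks always consume at least one symbol
            return
        if i < n and j < m:
            rec(i + 1, j + 1, g + gain(("M", i + 1, j + 1)))
        if i < n:
            rec(i + 1, j, g + gain(("X", i + 1, j)))
        if j < m:
            rec(i, j + 1, g + gain(("Y", i, j + 1)))
        for (a1, a2, b1, b2) in cand:
            if a1 == i and b1 == j:
                rec(a2, b2, g + gain(("R", a1, a2, b1, b2)))

    rec(0, 0, 0.0)
    return best[0]


def enum_best_structure(sff, X, Y, candidates):
    """Most probable block structure and its probability."""
    structures = enum_block_structures(sff, X, Y, candidates)
    if not structures:
        return None, 0.0
    return max(structures, key=lambda t: t[1])


# ----------------------------------------------------------- random models
def random_pair_hmm(rng, max_emitting: int = 5, with_context: bool = False,
                    with_repeat: bool = True) -> PairHMM:
    """A random valid pair HMM for property tests.

    Random emitting states of all classes, an optional silent chain, random
    sparse transitions renormalized to sum to one, a guaranteed nonzero
    direct start->end escape so every instance has positive probability.
    """
    model = PairHMM()
    k = int(rng.integers(2, max_emitting + 1))
    classes = [EmissionClass.BOTH, EmissionClass.X_ONLY, EmissionClass.Y_ONLY]
    names = []
    for idx in range(k):
        cls = classes[int(rng.integers(0, 3))]
        if cls == EmissionClass.BOTH:
            e = rng.random((4, 4)) + 0.05
            e /= e.sum()
            order = 0
        else:
            if with_context and rng.random() < 0.3:
                order = int(rng.integers(1, 3))
                e = rng.random((5, 4)) + 0.05
                e /= e.sum(axis=1, keepdims=True)
            else:
                order = 0
                e = rng.random(4) + 0.05
                e /= e.sum()
        name = f"s{idx}"
        model.add_state(name, cls, e, context_order=order,
                        repeat=bool(with_repeat and rng.random() < 0.4))
        names.append(name)
    nsil = int(rng.integers(0, 3))
    sil = []
    for idx in range(nsil):
        name = f"q{idx}"
        model.add_state(name, EmissionClass.SILENT)
        sil.append(name)
    everything = names + sil + ["end"]

    def targets_of(src):
        # silent states only point forward in the chain (acyclic)
        if src in sil:
            later = sil[sil.index(src) + 1:]
            return names + later + ["end"]
        return everything

    for src in ["start"] + names + sil:
        opts = targets_of(src)
        nt = int(rng.integers(1, min(4, len(opts)) + 1))
        chosen = list(rng.choice(len(opts), size=nt, replace=False))
        probs = rng.random(nt) + 0.1
        if src == "start" and "end" not in [opts[c] for c in chosen]:
            chosen.append(opts.index("end"))
            probs = np.append(probs, 0.05)
        probs /= probs.sum()
        for c, pr in zip(chosen, probs):
            model.add_transition(src, opts[c], float(pr))
    return model


def random_dna(rng, max_len: int = 3) -> str:
    length = int(rng.integers(0, max_len + 1))
    return "".join("ACGT"[int(c)] for c in rng.integers(0, 4, size=length))


def random_sff(rng, max_motifs: int = 2):
    """A random small SFF model (for oracle-equivalence trials)."""
    from sffalign.models import (MotifLibrary, SffModel, SunflowerParams,
                                 ThreeStateParams, jc_pair_emission)

    k = int(rng.integers(0, max_motifs + 1))
    motifs = []
    for _ in range(k):
        length = int(rng.integers(1, 3))
        motifs.append("".join("ACGT"[int(c)]
                              for c in rng.integers(0, 4, size=length)))
    motifs = list(dict.fromkeys(motifs))
    weights = rng.random(len(motifs)) + 0.2
    lib = MotifLibrary([(c, float(w / weights.sum()))
                        for c, w in zip(motifs, weights)])
    ts = ThreeStateParams(
        gap_open=float(rng.uniform(0.02, 0.15)),
        gap_extend=float(rng.uniform(0.1, 0.4)),
        end_prob=float(rng.uniform(0.1, 0.3)),
        match_emission=jc_pair_emission(float(rng.uniform(0.05, 0.5))))
    sun = SunflowerParams(
        insert_rate=float(rng.uniform(0.01, 0.1)),
        delete_rate=float(rng.uniform(0.01, 0.1)),
        t=float(rng.uniform(0.0, 0.3)),
        copy_continue=float(rng.uniform(0.3, 0.9)),
        motif_entry=float(rng.uniform(0.02, 0.15)))
    return SffModel(lib, ts, sun)


def labeled_alignment_gain(ref, aln, labels):
    """Total gain of a labeled alignment under an oracle posterior dict."""
    g = 0.0
    i = j = 0
    for mv, lab in zip(aln.moves, labels):
        if mv != 2:
            i += 1
        if mv != 1:
            j += 1
        g += ref.get((int(mv), i, j, int(lab)), 0.0)
    return g


def marginalized_ref(ref, n, m):
    """Marginalize gap-column posteriors of an oracle dict over placements."""
    out = dict(ref)
    for lab in (0, 1):
        for i in range(1, n + 1):
            s = sum(ref.get((1, i, j, lab), 0.0) for j in range(m + 1))
            for j in range(m + 1):
                out[(1, i, j, lab)] = s
        for j in range(1, m + 1):
            s = sum(ref.get((2, i, j, lab), 0.0) for i in range(n + 1))
            for i in range(n + 1):
                out[(2, i, j, lab)] = s
    return out


def tiling_gain(post, aln, labels, blocks):
    """Gain of a block-decode result under oracle item posteriors."""
    g = 0.0
    for b in blocks:
        if b.label == 1:
            item = ("R", b.x[0], b.x[1], b.y[0], b.y[1])
            g += post.get(item, 0.0) * ((b.x[1] - b.x[0]) + (b.y[1] - b.y[0]))
    i = j = 0
    consumed = []
    for mv, lab in zip(aln.moves, labels):
        if mv != 2:
            i += 1
        if mv != 1:
            j += 1
        if lab == 0:
            kind = ("M", "X", "Y")[int(mv)]
            g += post.get((kind, i, j), 0.0)
    return g
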