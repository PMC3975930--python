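"""Generic pair hidden Markov models and the standard inference algorithms.

A :class:`PairHMM` is a sparse state graph. Each state has an emission class:

* ``BOTH`` — emits an aligned symbol pair (one symbol in each sequence),
* ``X_ONLY`` / ``Y_ONLY`` — emits a single symbol in one sequence
  (an alignment column against a gap),
* ``SILENT`` — emits nothing (start/end and structural states).

Single-sequence states may carry a context order k > 0, in which case the
emission distribution is conditioned on the symbol k positions earlier in the
same sequence (with a background fallback where that symbol does not exist).

The module provides model validation, forward/backward, Viterbi, per-state
column posteriors, path sampling and exact JSON round-tripping. All
probability computations run in log space on a compiled lattice.
"""
from __future__ import annotations

import enum
import graphlib
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _engine
from ._alphabet import ALPHABET, decode, encode
from .errors import InputError, ModelError, ZeroProbabilityError

PROB_TOL = 1e-9          # tolerance for probability sums
DP_REL_TOL = 1e-6        # tolerance for DP identities (forward == backward)


class EmissionClass(enum.IntEnum):
    BOTH = _engine.CLS_BOTH
    X_ONLY = _engine.CLS_X
    Y_ONLY = _engine.CLS_Y
    SILENT = _engine.CLS_SILENT


@dataclass
class _Compiled:
    """Array form of a PairHMM consumed by the numba kernels."""

    index: dict
    cls: np.ndarray
    ctxk: np.ndarray
    le_pair: np.ndarray
    le_single: np.ndarray
    proc_fwd: np.ndarray
    proc_bwd: np.ndarray
    tin_ptr: np.ndarray
    tin_src: np.ndarray
    tin_logp: np.ndarray
    tin_edges: list
    out_ptr: np.ndarray
    out_dst: np.ndarray
    out_logp: np.ndarray
    start: int
    end: int
    repeat: np.ndarray


class PairHMM:
    """Sparse pair HMM over the DNA alphabet.

    Parameters
    ----------
    start, end : str
        Names of the (silent) start and end states. They are created
        automatically.
    """

    def __init__(self, start: str = "start", end: str = "end"):
        self.states: list[str] = []
        self.emission_class: dict[str, EmissionClass] = {}
        self.emissions: dict[str, np.ndarray] = {}
        self.context_order: dict[str, int] = {}
        self.transitions: dict[str, dict[str, float]] = {}
        self.state_meta: dict[str, dict] = {}
        self.start = start
        self.end = end
        self.meta: dict = {}
        self._compiled: _Compiled | None = None
        self.add_state(start, EmissionClass.SILENT)
        self.add_state(end, EmissionClass.SILENT)

    # ------------------------------------------------------------------ build
    def add_state(self, name: str, cls: EmissionClass,
                  emission: np.ndarray | None = None,
                  context_order: int = 0, **meta) -> None:
        if name in self.emission_class:
            raise ModelError(f"duplicate state {name!r}")
        self.states.append(name)
        self.emission_class[name] = EmissionClass(cls)
        if emission is not None:
            emission = np.asarray(emission, dtype=float)
        self.emissions[name] = emission
        self.context_order[name] = int(context_order)
        self.transitions.setdefault(name, {})
        self.state_meta[name] = dict(meta)
        self._compiled = None

    def add_transition(self, src: str, dst: str, prob: float) -> None:
        if src not in self.emission_class or dst not in self.emission_class:
            raise ModelError(f"transition references unknown state {src!r}->{dst!r}")
        if prob < 0:
            raise ModelError(f"negative transition probability {src!r}->{dst!r}")
        if prob > 0.0:
            self.transitions.setdefault(src, {})
            self.transitions[src][dst] = self.transitions[src].get(dst, 0.0) + prob
            self._compiled = None

    def is_repeat_state(self, name: str) -> bool:
        return bool(self.state_meta.get(name, {}).get("repeat", False))

    def is_emitting(self, name: str) -> bool:
        return self.emission_class[name] != EmissionClass.SILENT

    # -------------------------------------------------------------- serialise
    def to_json(self) -> str:
        def emis(name):
            e = self.emissions[name]
            return None if e is None else e.tolist()

        obj = {
            "start": self.start,
            "end": self.end,
            "meta": self.meta,
            "states": [
                {
                    "name": s,
                    "class": self.emission_class[s].name,
                    "context_order": self.context_order[s],
                    "emission": emis(s),
                    "meta": self.state_meta[s],
                }
                for s in self.states
            ],
            "transitions": [
                [src, dst, p]
                for src in self.states
                for dst, p in sorted(self.transitions.get(src, {}).items())
            ],
        }
        return json.dumps(obj, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PairHMM":
        obj = json.loads(text)
        model = cls.__new__(cls)
        model.states = []
        model.emission_class = {}
        model.emissions = {}
        model.context_order = {}
        model.transitions = {}
        model.state_meta = {}
        model.start = obj["start"]
        model.end = obj["end"]
        model.meta = obj.get("meta", {})
        model._compiled = None
        for st in obj["states"]:
            model.add_state(
                st["name"], EmissionClass[st["class"]],
                None if st["emission"] is None else np.array(st["emission"]),
                st["context_order"], **st.get("meta", {}))
        for src, dst, p in obj["transitions"]:
            model.add_transition(src, dst, p)
        return model

    # ---------------------------------------------------------------- compile
    def compiled(self) -> _Compiled:
        if self._compiled is None:
            self._compiled = _compile(self)
        return self._compiled


def _silent_topo_order(model: PairHMM) -> list[str]:
    """Topological order of the silent-state subgraph (raises on a cycle)."""
    silent = [s for s in model.states
              if model.emission_class[s] == EmissionClass.SILENT]
    ts = graphlib.TopologicalSorter({s: [] for s in silent})
    for src in silent:
        for dst in model.transitions.get(src, {}):
            if dst in model.emission_class and \
                    model.emission_class[dst] == EmissionClass.SILENT:
                ts.add(dst, src)
    try:
        order = [s for s in ts.static_order() if s in set(silent)]
    except graphlib.CycleError as exc:
        raise ModelError(f"silent cycle: {exc.args[1]}") from exc
    return order


def _emission_arrays(model: PairHMM, index: Mapping[str, int]):
    ns = len(model.states)
    le_pair = np.full((ns, 4, 4), _engine.NEG_INF)
    le_single = np.full((ns, 5, 4), _engine.NEG_INF)
    with np.errstate(divide="ignore"):
        for s in model.states:
            i = index[s]
            cls = model.emission_class[s]
            e = model.emissions[s]
            if cls == EmissionClass.SILENT or e is None:
                continue
            if cls == EmissionClass.BOTH:
                le_pair[i] = np.log(np.asarray(e, dtype=float))
            else:
                e = np.asarray(e, dtype=float)
                if e.ndim == 1:
                    le_single[i] = np.log(np.tile(e, (5, 1)))
                else:
                    le_single[i] = np.log(e)
    return le_pair, le_single


def _compile(model: PairHMM) -> _Compiled:
    violations = validate_model(model)
    if violations:
        raise ModelError("invalid model: " + "; ".join(violations))
    index = {s: i for i, s in enumerate(model.states)}
    ns = len(model.states)
    cls = np.array([int(model.emission_class[s]) for s in model.states],
                   dtype=np.int8)
    ctxk = np.array([model.context_order[s] for s in model.states],
                    dtype=np.int64)
    le_pair, le_single = _emission_arrays(model, index)

    topo = _silent_topo_order(model)
    emitting = [s for s in model.states if model.is_emitting(s)]
    proc_fwd = np.array(
        [index[s] for s in emitting] +
        [index[s] for s in topo if s != model.start],
        dtype=np.int64)
    # forward processes emitting states first, then silent in topo order;
    # backward processes silent states in reverse topo order, then emitting.
    proc_bwd = np.array(
        [index[s] for s in reversed(topo) if s != model.end] +
        [index[s] for s in emitting],
        dtype=np.int64)

    edges = []
    for src in model.states:
        for dst, p in model.transitions.get(src, {}).items():
            edges.append((index[src], index[dst], math.log(p)))
    # by target, sources in declaration order (deterministic Viterbi ties)
    by_t = sorted(edges, key=lambda e: (e[1], e[0]))
    tin_ptr = np.zeros(ns + 1, dtype=np.int64)
    tin_src = np.array([e[0] for e in by_t], dtype=np.int64)
    tin_logp = np.array([e[2] for e in by_t], dtype=float)
    for e in by_t:
        tin_ptr[e[1] + 1] += 1
    tin_ptr = np.cumsum(tin_ptr)
    by_s = sorted(edges, key=lambda e: (e[0], e[1]))
    out_ptr = np.zeros(ns + 1, dtype=np.int64)
    out_dst = np.array([e[1] for e in by_s], dtype=np.int64)
    out_logp = np.array([e[2] for e in by_s], dtype=float)
    for e in by_s:
        out_ptr[e[0] + 1] += 1
    out_ptr = np.cumsum(out_ptr)

    if len(by_t) and int(np.diff(tin_ptr).max()) > 32000:
        raise ModelError("a state has too many incoming transitions (>32000)")
    repeat = np.array([1 if model.is_repeat_state(s) else 0
                       for s in model.states], dtype=np.uint8)
    return _Compiled(index=index, cls=cls, ctxk=ctxk, le_pair=le_pair,
                     le_single=le_single, proc_fwd=proc_fwd,
                     proc_bwd=proc_bwd, tin_ptr=tin_ptr, tin_src=tin_src,
                     tin_logp=tin_logp, tin_edges=by_t, out_ptr=out_ptr,
                     out_dst=out_dst, out_logp=out_logp,
                     start=index[model.start], end=index[model.end],
                     repeat=repeat)


# ---------------------------------------------------------------- validation
def validate_model(model: PairHMM) -> list[str]:
    """Diagnose structural problems; returns an empty list iff valid."""
    out: list[str] = []
    for s in model.states:
        cls = model.emission_class[s]
        if s != model.end:
            total = sum(model.transitions.get(s, {}).values())
            if not math.isclose(total, 1.0, rel_tol=0, abs_tol=PROB_TOL):
                out.append(f"outgoing probabilities of state {s!r} sum to {total:.12g}")
        for dst, p in model.transitions.get(s, {}).items():
            if not (0.0 <= p <= 1.0 + PROB_TOL):
                out.append(f"transition {s!r}->{dst!r} probability {p} outside [0,1]")
            if dst == model.start:
                out.append(f"transition {s!r}->{dst!r} enters the start state")
        e = model.emissions[s]
        if cls == EmissionClass.SILENT:
            if e is not None:
                out.append(f"silent state {s!r} carries an emission table")
            continue
        if e is None:
            out.append(f"state {s!r} has no emission table")
            continue
        e = np.asarray(e, dtype=float)
        if cls == EmissionClass.BOTH:
            if e.shape != (4, 4):
                out.append(f"state {s!r} emission table shape {e.shape} != (4, 4)")
            elif not math.isclose(e.sum(), 1.0, rel_tol=0, abs_tol=PROB_TOL):
                out.append(f"state {s!r} emission table sums to {e.sum():.12g}")
            if model.context_order[s] != 0:
                out.append(f"context order on BOTH state {s!r}")
        else:
            rows = e.reshape(1, -1) if e.ndim == 1 else e
            for r, row in enumerate(rows):
                if not math.isclose(row.sum(), 1.0, rel_tol=0, abs_tol=PROB_TOL):
                    out.append(f"state {s!r} emission row {r} sums to {row.sum():.12g}")
            if model.context_order[s] > 0 and e.ndim != 2:
                out.append(f"state {s!r} has context order but a single emission row")
        if model.context_order[s] < 0:
            out.append(f"state {s!r} has negative context order")
    try:
        _silent_topo_order(model)
    except ModelError as exc:
        out.append(str(exc))
    for s in (model.start, model.end):
        if model.emission_class[s] != EmissionClass.SILENT:
            out.append(f"state {s!r} must be silent")
    return out


# ----------------------------------------------------------------- inference
@dataclass
class DpTables:
    """Forward/backward lattices (log space) for one (model, X, Y) instance."""

    model: PairHMM
    x: np.ndarray
    y: np.ndarray
    forward: np.ndarray          # (n_states, n+1, m+1)
    backward: np.ndarray
    log_total_forward: float
    log_total_backward: float

    @property
    def log_total(self) -> float:
        return self.log_total_forward

    def state_value(self, table: np.ndarray, state: str) -> np.ndarray:
        return table[self.model.compiled().index[state]]


def _prepare(model: PairHMM, X, Y, band=None):
    comp = model.compiled()
    x = X if isinstance(X, np.ndarray) else encode(X)
    y = Y if isinstance(Y, np.ndarray) else encode(Y)
    if band is None:
        allowed = np.ones((len(x) + 1, len(y) + 1), dtype=np.uint8)
    else:
        allowed = np.asarray(
            band.to_array(len(x), len(y)) if hasattr(band, "to_array") else band,
            dtype=np.uint8)
        if allowed.shape != (len(x) + 1, len(y) + 1):
            raise InputError("band mask shape does not match sequence lengths")
    return comp, x, y, allowed


def forward_backward(model: PairHMM, X, Y, band=None) -> DpTables:
    """Full forward and backward lattices and the total log-probability."""
    comp, x, y, allowed = _prepare(model, X, Y, band)
    F = _engine.forward_kernel(comp.cls, comp.ctxk, comp.le_pair,
                               comp.le_single, comp.proc_fwd, comp.tin_ptr,
                               comp.tin_src, comp.tin_logp, comp.start,
                               x, y, allowed)
    B = _engine.backward_kernel(comp.cls, comp.ctxk, comp.le_pair,
                                comp.le_single, comp.proc_bwd, comp.out_ptr,
                                comp.out_dst, comp.out_logp, comp.end,
                                x, y, allowed)
    total_f = float(F[len(x), len(y), comp.end])
    total_b = float(B[0, 0, comp.start])
    # (state, i, j) views over the kernel's (i, j, state) storage
    return DpTables(model=model, x=x, y=y,
                    forward=np.moveaxis(F, 2, 0),
                    backward=np.moveaxis(B, 2, 0),
                    log_total_forward=total_f, log_total_backward=total_b)


def viterbi_path(model: PairHMM, X, Y, band=None):
    """Most probable generating state path.

    Returns ``(path, log_prob)`` where ``path`` is the state-name sequence
    (silent states included, start/end excluded). If no path generates the
    pair the log-probability is -inf and the path is empty.
    """
    comp, x, y, allowed = _prepare(model, X, Y, band)
    Vlast, bp = _engine.viterbi_lowmem_kernel(
        comp.cls, comp.ctxk, comp.le_pair, comp.le_single, comp.proc_fwd,
        comp.tin_ptr, comp.tin_src, comp.tin_logp, comp.start, x, y, allowed)
    n, m = len(x), len(y)
    logp = float(Vlast[m, comp.end])
    if logp == _engine.NEG_INF:
        return [], _engine.NEG_INF
    names = model.states
    path = []
    s, i, j = comp.end, n, m
    while not (s == comp.start and i == 0 and j == 0):
        e = bp[i, j, s]
        if e < 0:
            raise ModelError("viterbi traceback failed")
        c = comp.cls[s]
        path.append(names[s])
        if c == _engine.CLS_BOTH:
            i, j = i - 1, j - 1
        elif c == _engine.CLS_X:
            i = i - 1
        elif c == _engine.CLS_Y:
            j = j - 1
        s = comp.tin_src[comp.tin_ptr[s] + e]
    path.reverse()
    return path[:-1], logp  # drop the end state


def state_column_posteriors(model: PairHMM, X, Y, band=None,
                            tables: DpTables | None = None) -> np.ndarray:
    """Posterior that state s emits the column at lattice cell (i, j).

    Returns an array of shape (n_states, n+1, m+1) in linear probability
    space; silent-state entries are zero. Entry (s, i, j) is the posterior
    probability that a path emits x_i (and/or y_j) from state s, i.e. sums of
    posteriors over all columns consuming a given x_i equal one.
    """
    if tables is None:
        tables = forward_backward(model, X, Y, band)
    comp = model.compiled()
    Z = tables.log_total_forward
    if Z == _engine.NEG_INF:
        raise ZeroProbabilityError("model assigns zero probability to (X, Y)")
    P = np.zeros_like(tables.forward)
    emitting = comp.cls != _engine.CLS_SILENT
    with np.errstate(invalid="ignore"):
        vals = tables.forward[emitting] + tables.backward[emitting] - Z
    vals[np.isnan(vals)] = _engine.NEG_INF
    P[emitting] = np.exp(vals)
    return P


# ------------------------------------------------------------------ sampling
def _end_reachable(model: PairHMM) -> bool:
    seen = {model.start}
    stack = [model.start]
    while stack:
        s = stack.pop()
        for dst in model.transitions.get(s, {}):
            if dst not in seen:
                seen.add(dst)
                stack.append(dst)
    return model.end in seen


def sample_path(model: PairHMM, rng_seed) -> tuple[str, str, "object", list[str]]:
    """Sample (X, Y, alignment, state path) from the model.

    ``rng_seed`` may be an integer seed or a ``numpy.random.Generator``.
    The returned alignment is an :class:`sffalign.alignment.Alignment`
    consistent with the emitted sequences and state path.
    """
    from .alignment import alignment_from_state_path

    violations = validate_model(model)
    if violations:
        raise ModelError("invalid model: " + "; ".join(violations))
    if not _end_reachable(model):
        raise ModelError("end state unreachable from start")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    xs: list[int] = []
    ys: list[int] = []
    path: list[str] = []
    s = model.start
    max_steps = 10_000_000
    for _ in range(max_steps):
        dsts = list(model.transitions[s].keys())
        probs = np.array([model.transitions[s][d] for d in dsts])
        s = dsts[rng.choice(len(dsts), p=probs / probs.sum())]
        if s == model.end:
            break
        path.append(s)
        cls = model.emission_class[s]
        if cls == EmissionClass.SILENT:
            continue
        if cls == EmissionClass.BOTH:
            e = model.emissions[s].ravel()
            pair = rng.choice(16, p=e / e.sum())
            xs.append(pair // 4)
            ys.append(pair % 4)
        else:
            seq = xs if cls == EmissionClass.X_ONLY else ys
            e = model.emissions[s]
            if e.ndim == 2:
                k = model.context_order[s]
                row = e[seq[-k]] if (k > 0 and len(seq) >= k) else e[4]
            else:
                row = e
            seq.append(int(rng.choice(4, p=row / row.sum())))
    else:
        raise ModelError("sampling exceeded the step limit")
    X = decode(xs)
    Y = decode(ys)
    aln = alignment_from_state_path(model, path, len(xs), len(ys))
    return X, Y, aln, path
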