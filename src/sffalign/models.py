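"""Builders for the concrete alignment models.

* the classical three-state pair HMM (match + two insert states),
* "sunflower" submodels: circular profile HMMs emitting tandem copies of a
  fixed motif in one sequence, with a geometric copy count,
* the SFF ("sunflower field") model: the three-state core plus an X-side and
  a Y-side sunflower for every motif in a library,
* the SRF single-sequence repeat finder (sunflower + background state),
* a TANTAN-style pair model in which a single order-k state per period
  captures tandem repetition.

Repeat submodels are entered from a silent "hub" state that follows the
start state, every match emission and every repeat exit; insert states do
not enter repeats. With an empty motif library the SFF reduces exactly to
the three-state model.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._alphabet import ALPHABET, _CODE
from .errors import ParameterError
from .hmm import EmissionClass, PairHMM

HUB = "hub"


# ------------------------------------------------------------- substitution
def jc_substitution(consensus_base: str | int, t: float) -> np.ndarray:
    """Jukes-Cantor substitution distribution after time t.

    Returns the distribution over A,C,G,T of a base that started as
    ``consensus_base``: the consensus base keeps probability
    1/4 + (3/4) e^(-4t/3) and each other base gets (1/4)(1 - e^(-4t/3)).
    """
    if t < 0:
        raise ParameterError(f"substitution time t={t} must be nonnegative")
    b = _CODE[consensus_base.upper()] if isinstance(consensus_base, str) \
        else int(consensus_base)
    e = math.exp(-4.0 * t / 3.0)
    dist = np.full(4, 0.25 * (1.0 - e))
    dist[b] = 0.25 + 0.75 * e
    return dist


def jc_pair_emission(t: float, background: np.ndarray | None = None) -> np.ndarray:
    """Joint emission over aligned base pairs: ancestor from the background,
    descendant by Jukes-Cantor divergence t."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    table = np.empty((4, 4))
    for a in range(4):
        table[a] = bg[a] * jc_substitution(a, t)
    return table


# ------------------------------------------------------------------- params
@dataclass
class ThreeStateParams:
    """Parameters of the three-state pair HMM.

    gap_open/gap_extend follow the usual affine-gap interpretation
    (M->I and I->I transition probabilities); ``end_prob`` is the
    termination probability from every state, which sets the expected
    alignment length to roughly 1/end_prob columns.
    """

    gap_open: float = 0.007
    gap_extend: float = 0.3
    end_prob: float = 0.005
    match_emission: np.ndarray = field(default_factory=lambda: jc_pair_emission(0.3))
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def validate(self) -> None:
        if not (0 <= self.gap_open and 2 * self.gap_open + self.end_prob <= 1):
            raise ParameterError("gap_open/end_prob out of range")
        if not (0 <= self.gap_extend and self.gap_extend + self.end_prob <= 1):
            raise ParameterError("gap_extend/end_prob out of range")

    # transition rows; the start state behaves like M
    @property
    def m_row(self) -> dict[str, float]:
        return {"M": 1.0 - 2 * self.gap_open - self.end_prob,
                "IX": self.gap_open, "IY": self.gap_open,
                "end": self.end_prob}

    def i_row(self, which: str) -> dict[str, float]:
        return {which: self.gap_extend,
                "M": 1.0 - self.gap_extend - self.end_prob,
                "end": self.end_prob}


@dataclass
class SunflowerParams:
    """Parameters shared by all sunflower (circular profile HMM) submodels."""

    insert_rate: float = 0.005
    delete_rate: float = 0.005
    t: float = 0.05                  # Jukes-Cantor divergence from consensus
    copy_continue: float = 0.85      # geometric copy-count parameter
    motif_entry: float = 0.01        # hub -> repeat submodels, split by priors

    def validate(self) -> None:
        for name in ("insert_rate", "delete_rate", "copy_continue", "motif_entry"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name}={v} outside [0,1]")
        if self.t < 0:
            raise ParameterError(f"t={self.t} must be nonnegative")
        if self.insert_rate + self.delete_rate > 1.0:
            raise ParameterError("insert_rate + delete_rate > 1")


@dataclass
class TantanParams:
    """Parameters of the TANTAN-style repeat submodel (periods 1..K)."""

    K: int = 50
    p_r: float = 0.1     # prefix -> repeat state (same for every period)
    p_ES: float = 0.05   # indel state -> end
    p_ER: float = 0.05   # repeat state -> end
    p_EI: float = 0.05   # init state -> end
    p_S: float = 0.01    # start an indel
    p_SE: float = 0.3    # extend an indel
    t: float = 0.05      # conservation of the symbol one period back
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    entry: float = 0.01  # hub -> repeat submodels

    def validate(self) -> None:
        if self.K < 1:
            raise ParameterError("K must be >= 1")
        for name in ("p_r", "p_ES", "p_ER", "p_EI", "p_S", "p_SE", "entry"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name}={v} outside [0,1]")
        if self.p_ER + 2 * self.p_S > 1 or self.p_SE + self.p_ES > 1 \
                or self.p_r + self.p_EI > 1:
            raise ParameterError("repeat/indel/prefix transition rows exceed 1")
        if self.t < 0:
            raise ParameterError("t must be nonnegative")


# ------------------------------------------------------------ motif library
@dataclass
class MotifLibrary:
    """Consensus motifs with normalized prior weights."""

    motifs: list[tuple[str, float]]

    def __post_init__(self):
        cleaned = []
        for consensus, w in self.motifs:
            consensus = consensus.upper()
            if not consensus or any(c not in ALPHABET for c in consensus):
                raise ParameterError(f"bad consensus {consensus!r}")
            if w < 0:
                raise ParameterError(f"negative prior for {consensus!r}")
            cleaned.append((consensus, float(w)))
        total = sum(w for _, w in cleaned)
        if cleaned and abs(total - 1.0) > 1e-9:
            raise ParameterError(f"priors sum to {total:.12g}, expected 1")
        self.motifs = cleaned

    def __len__(self) -> int:
        return len(self.motifs)

    @property
    def consensuses(self) -> list[str]:
        return [c for c, _ in self.motifs]

    @property
    def priors(self) -> np.ndarray:
        return np.array([w for _, w in self.motifs])


def motif_prior_from_counts(counts: Mapping[str, float]) -> MotifLibrary:
    """Library with priors proportional to observed consensus counts."""
    total = float(sum(counts.values()))
    if total <= 0:
        raise ParameterError("all motif counts are zero")
    for c, v in counts.items():
        if v < 0:
            raise ParameterError(f"negative count for {c!r}")
    return MotifLibrary([(c, v / total) for c, v in counts.items() if v > 0])


def default_motif_library() -> MotifLibrary:
    """A small built-in library of common short tandem repeat motifs
    (lengths 2-12), with frequency-like counts decreasing in motif length."""
    counts = {
        "AC": 30, "AAG": 24, "GATA": 20, "AATAG": 15, "TTAGGG": 11,
        "ACTCCAT": 8, "ATCTGGCA": 6, "AGGTCATTG": 5, "ACGTTAGCAT": 4,
        "AATGCTAGGTCA": 2,
    }
    return motif_prior_from_counts(counts)


# ------------------------------------------------------------- three-state
def build_three_state(params: ThreeStateParams | None = None) -> PairHMM:
    """The classical three-state pair HMM (match, X-insert, Y-insert)."""
    params = params or ThreeStateParams()
    params.validate()
    model = PairHMM()
    model.add_state("M", EmissionClass.BOTH, params.match_emission, role="match")
    model.add_state("IX", EmissionClass.X_ONLY, params.background, role="insert")
    model.add_state("IY", EmissionClass.Y_ONLY, params.background, role="insert")
    for dst, p in params.m_row.items():
        model.add_transition("start", dst, p)
        model.add_transition("M", dst, p)
    for s in ("IX", "IY"):
        for dst, p in params.i_row(s).items():
            model.add_transition(s, dst, p)
    return model


# ---------------------------------------------------------------- sunflower
def build_sunflower(motif: str, params: SunflowerParams | None = None,
                    background: np.ndarray | None = None,
                    prefix: str = "R") -> PairHMM:
    """Single-sequence circular profile HMM emitting tandem motif copies.

    States are X_ONLY; the fragment runs from silent entry ``<prefix>:s`` to
    silent exit ``<prefix>:e``. Match state M_j emits the j-th consensus
    symbol diverged by Jukes-Cantor time t; insert states emit the
    background. Two delete chains bypass match states: D'_0..D'_{p-2} is
    enterable only from the entry state and D_1..D_{p-1} only after a match
    or insert in the current copy, so no silent cycle can complete a period.
    The wrap-around from column p-1 to column 0 carries the copy-continue
    probability; its complement exits, which makes the copy count geometric.
    """
    params = params or SunflowerParams()
    params.validate()
    motif = motif.upper()
    if not motif or any(c not in ALPHABET for c in motif):
        raise ParameterError(f"bad motif {motif!r}")
    p = len(motif)
    ins, dele, cont = params.insert_rate, params.delete_rate, params.copy_continue
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)

    model = PairHMM(start=f"{prefix}:s", end=f"{prefix}:e")
    meta = dict(repeat=True, motif=motif, period=p)
    for s in (model.start, model.end):
        model.state_meta[s].update(meta)
    model.state_meta[model.start]["role"] = "entry"
    model.state_meta[model.end]["role"] = "exit"

    def M(j):
        return f"{prefix}:M{j}"

    def I(j):
        return f"{prefix}:I{j}"

    for j in range(p):
        model.add_state(M(j), EmissionClass.X_ONLY,
                        jc_substitution(motif[j], params.t),
                        role="match", column=j, **meta)
        model.add_state(I(j), EmissionClass.X_ONLY, bg,
                        role="insert", column=j, **meta)
    for j in range(1, p):
        model.add_state(f"{prefix}:D{j}", EmissionClass.SILENT,
                        role="delete", column=j, **meta)
    for j in range(p - 1):
        model.add_state(f"{prefix}:Dp{j}", EmissionClass.SILENT,
                        role="delete_entry", column=j, **meta)

    wrap = []

    def wrap_split(src, mass):
        # wrap-around into the next copy vs. exit
        model.add_transition(src, M(0), mass * cont)
        model.add_transition(src, model.end, mass * (1.0 - cont))
        wrap.append([src, M(0)])

    # entry: M_0 or the entry delete chain
    if p == 1:
        model.add_transition(model.start, M(0), 1.0)
    else:
        model.add_transition(model.start, M(0), 1.0 - dele)
        model.add_transition(model.start, f"{prefix}:Dp0", dele)
    # match and insert columns
    for j in range(p):
        last = j == p - 1
        model.add_transition(M(j), I(j), ins)
        model.add_transition(I(j), I(j), ins)
        if last:
            wrap_split(M(j), 1.0 - ins)
            wrap_split(I(j), 1.0 - ins)
        else:
            model.add_transition(M(j), f"{prefix}:D{j + 1}", dele)
            model.add_transition(M(j), M(j + 1), 1.0 - ins - dele)
            model.add_transition(I(j), f"{prefix}:D{j + 1}", dele)
            model.add_transition(I(j), M(j + 1), 1.0 - ins - dele)
    # in-copy delete chain D_1..D_{p-1}
    for j in range(1, p):
        src = f"{prefix}:D{j}"
        if j == p - 1:
            wrap_split(src, 1.0)
        else:
            model.add_transition(src, f"{prefix}:D{j + 1}", dele)
            model.add_transition(src, M(j + 1), 1.0 - dele)
    # entry delete chain D'_0..D'_{p-2}; cannot delete the whole first copy
    for j in range(p - 1):
        src = f"{prefix}:Dp{j}"
        if j == p - 2:
            model.add_transition(src, M(j + 1), 1.0)
        else:
            model.add_transition(src, f"{prefix}:Dp{j + 1}", dele)
            model.add_transition(src, M(j + 1), 1.0 - dele)
    model.meta["wrap_edges"] = wrap
    return model


def _graft(model: PairHMM, fragment: PairHMM, rename, cls_map) -> None:
    """Copy a single-sequence fragment into ``model`` with renamed states and
    a possibly different emission side."""
    for s in fragment.states:
        cls = fragment.emission_class[s]
        model.add_state(rename(s), cls_map.get(cls, cls), fragment.emissions[s],
                        fragment.context_order[s], **fragment.state_meta[s])
    for src, row in fragment.transitions.items():
        for dst, p in row.items():
            model.add_transition(rename(src), rename(dst), p)
    for src, dst in fragment.meta.get("wrap_edges", []):
        model.meta.setdefault("wrap_edges", []).append([rename(src), rename(dst)])


# ---------------------------------------------------------------------- SFF
def build_sff(library: MotifLibrary, three_state: ThreeStateParams | None = None,
              sun: SunflowerParams | None = None) -> PairHMM:
    """The sunflower-field pair HMM.

    The three-state core is augmented, for every motif i in the library, with
    an X-side sunflower feeding its Y-side twin through a probability-1
    transition. Repeat submodels are entered from the hub with probability
    motif_entry * prior_i and exit back to the hub, so repeat copies in the
    two sequences are generated independently (geometric copy counts on each
    side). With an empty library the model is exactly the three-state PHMM.
    """
    three_state = three_state or ThreeStateParams()
    sun = sun or SunflowerParams()
    three_state.validate()
    sun.validate()
    eta = sun.motif_entry if len(library) else 0.0

    model = PairHMM()
    model.add_state(HUB, EmissionClass.SILENT, role="hub")
    model.add_state("M", EmissionClass.BOTH, three_state.match_emission, role="match")
    model.add_state("IX", EmissionClass.X_ONLY, three_state.background, role="insert")
    model.add_state("IY", EmissionClass.Y_ONLY, three_state.background, role="insert")
    model.add_transition("start", HUB, 1.0)
    model.add_transition("M", HUB, 1.0)
    for dst, p in three_state.m_row.items():
        model.add_transition(HUB, dst, (1.0 - eta) * p)
    for s in ("IX", "IY"):
        for dst, p in three_state.i_row(s).items():
            model.add_transition(s, dst, p)

    for i, (consensus, w) in enumerate(library.motifs):
        fx = build_sunflower(consensus, sun, three_state.background,
                             prefix=f"R{i}X")
        fy = build_sunflower(consensus, sun, three_state.background,
                             prefix=f"R{i}Y")
        for frag in (fx, fy):
            for s in frag.states:
                frag.state_meta[s]["motif_index"] = i
        for s in fx.states:
            fx.state_meta[s]["side"] = "X"
        for s in fy.states:
            fy.state_meta[s]["side"] = "Y"
        _graft(model, fx, lambda s: s, {})
        _graft(model, fy, lambda s: s,
               {EmissionClass.X_ONLY: EmissionClass.Y_ONLY})
        model.add_transition(HUB, f"R{i}X:s", eta * w)
        model.add_transition(f"R{i}X:e", f"R{i}Y:s", 1.0)
        model.add_transition(f"R{i}Y:e", HUB, 1.0)
    return model


@dataclass
class SffModel:
    """An SFF model bundled with the parameters it was built from.

    The block decoders and the simulator need the structured form (library,
    rates) as well as the flat pair HMM, so this wrapper keeps both.
    """

    library: MotifLibrary
    three_state: ThreeStateParams = field(default_factory=ThreeStateParams)
    sunflower: SunflowerParams = field(default_factory=SunflowerParams)
    _hmm: PairHMM | None = field(default=None, repr=False)

    @property
    def hmm(self) -> PairHMM:
        if self._hmm is None:
            self._hmm = build_sff(self.library, self.three_state, self.sunflower)
        return self._hmm

    @property
    def eta(self) -> float:
        return self.sunflower.motif_entry if len(self.library) else 0.0

    def x_fragment(self, i: int) -> PairHMM:
        return build_sunflower(self.library.consensuses[i], self.sunflower,
                               self.three_state.background, prefix=f"R{i}X")

    def y_fragment(self, i: int) -> PairHMM:
        return build_sunflower(self.library.consensuses[i], self.sunflower,
                               self.three_state.background, prefix=f"R{i}Y")


# ---------------------------------------------------------------------- SRF
def build_srf(motif: str, params: SunflowerParams | None = None,
              background: np.ndarray | None = None,
              stay: float = 0.99, enter: float = 0.005) -> PairHMM:
    """Sunflower repeat finder: one sunflower plus a background state B.

    A single-sequence HMM; Viterbi decoding labels maximal runs of sunflower
    states, which are reported as candidate repeat intervals. ``stay`` is the
    B self-loop, ``enter`` the B->sunflower probability (the remainder ends
    the sequence); the same row is used from the start state and from the
    sunflower exit so a repeat may touch either sequence end.
    """
    if stay < 0 or enter < 0 or stay + enter > 1:
        raise ParameterError("invalid SRF background transitions")
    params = params or SunflowerParams()
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    model = PairHMM()
    model.add_state("B", EmissionClass.X_ONLY, bg, role="background")
    frag = build_sunflower(motif, params, bg, prefix="R")
    _graft(model, frag, lambda s: s, {})
    row = {"B": stay, "R:s": enter, "end": 1.0 - stay - enter}
    for src in ("start", "B", "R:e"):
        for dst, p in row.items():
            model.add_transition(src, dst, p)
    return model


# ------------------------------------------------------------------- TANTAN
def _tantan_fragment(params: TantanParams, prefix: str) -> PairHMM:
    """One single-sequence TANTAN-style submodel for periods 1..K.

    A prefix chain P_1..P_K emits the first motif occurrence from the
    background; P_k hands over to the order-k repeat state R_k with the same
    probability p_r for every k. R_k emits each symbol conditioned on the
    symbol k positions earlier (Jukes-Cantor conservation, time t). Insert
    states I_k (k < K) lengthen the effective period by one; silent delete
    states D_k (k >= 2) shorten it by one.
    """
    params.validate()
    K = params.K
    bg = np.asarray(params.background, float)
    # context-conditioned emission: rows 0..3 = previous-period symbol,
    # row 4 = background fallback when the context symbol does not exist
    def r_emission():
        table = np.empty((5, 4))
        for c in range(4):
            table[c] = jc_substitution(c, params.t)
        table[4] = bg
        return table

    model = PairHMM(start=f"{prefix}:s", end=f"{prefix}:e")
    meta = dict(repeat=True)
    model.state_meta[model.start].update(meta, role="entry")
    model.state_meta[model.end].update(meta, role="exit")
    for k in range(1, K + 1):
        model.add_state(f"{prefix}:P{k}", EmissionClass.X_ONLY, bg,
                        role="prefix", period=k, **meta)
        model.add_state(f"{prefix}:R{k}", EmissionClass.X_ONLY, r_emission(),
                        context_order=k, role="repeat", period=k, **meta)
    for k in range(1, K):
        model.add_state(f"{prefix}:I{k}", EmissionClass.X_ONLY, bg,
                        role="insert", period=k, **meta)
    for k in range(2, K + 1):
        model.add_state(f"{prefix}:D{k}", EmissionClass.SILENT,
                        role="delete", period=k, **meta)

    # exit from the prefix ("init") path with p_EI; a pass through the
    # submodel always emits at least one symbol, which keeps the chained
    # X-side/Y-side pair model free of silent cycles
    model.add_transition(model.start, f"{prefix}:P1", 1.0)
    for k in range(1, K):
        model.add_transition(f"{prefix}:P{k}", f"{prefix}:R{k}", params.p_r)
        model.add_transition(f"{prefix}:P{k}", model.end, params.p_EI)
        model.add_transition(f"{prefix}:P{k}", f"{prefix}:P{k + 1}",
                             1.0 - params.p_r - params.p_EI)
    model.add_transition(f"{prefix}:P{K}", f"{prefix}:R{K}", 1.0 - params.p_EI)
    model.add_transition(f"{prefix}:P{K}", model.end, params.p_EI)
    for k in range(1, K + 1):
        r = f"{prefix}:R{k}"
        stay = 1.0 - params.p_ER
        if k < K:
            model.add_transition(r, f"{prefix}:I{k}", params.p_S)
            stay -= params.p_S
        if k >= 2:
            model.add_transition(r, f"{prefix}:D{k}", params.p_S)
            stay -= params.p_S
        model.add_transition(r, r, stay)
        model.add_transition(r, model.end, params.p_ER)
    for k in range(1, K):
        i = f"{prefix}:I{k}"
        model.add_transition(i, i, params.p_SE)
        model.add_transition(i, model.end, params.p_ES)
        model.add_transition(i, f"{prefix}:R{k + 1}",
                             1.0 - params.p_SE - params.p_ES)
    for k in range(2, K + 1):
        model.add_transition(f"{prefix}:D{k}", f"{prefix}:R{k - 1}", 1.0)
    return model


def build_tantan_pair(params: TantanParams | None = None,
                      three_state: ThreeStateParams | None = None) -> PairHMM:
    """Three-state core plus an X-side and a Y-side TANTAN submodel.

    Like the SFF, a repeat event first emits the repeat in X and then in Y,
    entered from the hub with probability ``params.entry``.
    """
    params = params or TantanParams()
    three_state = three_state or ThreeStateParams()
    params.validate()
    three_state.validate()
    eta = params.entry
    model = PairHMM()
    model.add_state(HUB, EmissionClass.SILENT, role="hub")
    model.add_state("M", EmissionClass.BOTH, three_state.match_emission, role="match")
    model.add_state("IX", EmissionClass.X_ONLY, three_state.background, role="insert")
    model.add_state("IY", EmissionClass.Y_ONLY, three_state.background, role="insert")
    model.add_transition("start", HUB, 1.0)
    model.add_transition("M", HUB, 1.0)
    for dst, p in three_state.m_row.items():
        model.add_transition(HUB, dst, (1.0 - eta) * p)
    for s in ("IX", "IY"):
        for dst, p in three_state.i_row(s).items():
            model.add_transition(s, dst, p)
    tx = _tantan_fragment(params, "TX")
    ty = _tantan_fragment(params, "TY")
    for s in tx.states:
        tx.state_meta[s]["side"] = "X"
    for s in ty.states:
        ty.state_meta[s]["side"] = "Y"
    _graft(model, tx, lambda s: s, {})
    _graft(model, ty, lambda s: s,
           {EmissionClass.X_ONLY: EmissionClass.Y_ONLY})
    model.add_transition(HUB, "TX:s", eta)
    model.add_transition("TX:e", "TY:s", 1.0)
    model.add_transition("TY:e", HUB, 1.0)
    return model
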