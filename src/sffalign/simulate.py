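"""Sampling benchmark datasets from the SFF model and scoring decoders.

The simulator draws (X, Y, true alignment, true state path, true repeat
annotation) instances from an SFF model and applies the benchmark
constraints by rejection: a minimum alignment length and a minimum number
of motif copies per repeat in each sequence (so that accepted repeats are
genuine tandem arrays rather than single motif occurrences).

Four accuracy measures are provided:

* alignment error rate — fraction of true non-repeat alignment columns
  (gap annotation included in column identity) missing from the prediction;
* per-base repeat sensitivity/specificity, pooled over both sequences;
* repeat-block sensitivity/specificity, requiring exact interval-pair
  equality;
* alignment error as a function of the column distance to the nearest true
  repeat block.

Dataset-level numbers are pooled counts (micro-averages), not means of
per-instance rates.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .alignment import (Alignment, Block, RepeatAnnotation,
                        blocks_from_annotation)
from .errors import ConfigurationError, InputError
from .hmm import PairHMM, sample_path
from .models import SffModel

REJECTION_CAP = 100_000


@dataclass
class RepeatRecord:
    """Generation record of one repeat event (one pass through a motif's
    X-side and Y-side submodels)."""

    motif: str
    motif_index: int
    copies_x: int
    copies_y: int
    x_interval: tuple[int, int]
    y_interval: tuple[int, int]
    column_interval: tuple[int, int]


@dataclass
class SimulatedInstance:
    x: str
    y: str
    alignment: Alignment
    state_path: list[str]
    annotation: RepeatAnnotation
    repeats: list[RepeatRecord]
    seed: int | None = None


def _wrap_edge_set(model: PairHMM) -> set[tuple[str, str]]:
    return {tuple(e) for e in model.meta.get("wrap_edges", [])}


def _repeat_records(model: PairHMM, path: Sequence[str]) -> list[RepeatRecord]:
    wraps = _wrap_edge_set(model)
    meta = model.state_meta
    records: list[RepeatRecord] = []
    i = j = col = 0
    t = 0
    cur = None  # (motif_index, motif, x0, y0, col0, copies_x, copies_y)
    prev = None
    for s in path:
        m = meta.get(s, {})
        emitting = model.is_emitting(s)
        if m.get("repeat"):
            if cur is None or m.get("motif_index") != cur["idx"]:
                if cur is not None:
                    records.append(_close_record(cur, i, j, col))
                cur = dict(idx=m.get("motif_index"), motif=m.get("motif"),
                           x0=i, y0=j, c0=col, wx=0, wy=0,
                           seen_x=False, seen_y=False)
            if prev is not None and (prev, s) in wraps:
                if m.get("side") == "X":
                    cur["wx"] += 1
                else:
                    cur["wy"] += 1
            if emitting:
                if m.get("side") == "X":
                    cur["seen_x"] = True
                else:
                    cur["seen_y"] = True
        else:
            if cur is not None:
                records.append(_close_record(cur, i, j, col))
                cur = None
        if emitting:
            cls = model.emission_class[s].name
            if cls in ("BOTH", "X_ONLY"):
                i += 1
            if cls in ("BOTH", "Y_ONLY"):
                j += 1
            col += 1
        prev = s
    if cur is not None:
        records.append(_close_record(cur, i, j, col))
    return records


def _close_record(cur, i, j, col) -> RepeatRecord:
    return RepeatRecord(
        motif=cur["motif"], motif_index=cur["idx"],
        copies_x=cur["wx"] + (1 if cur["seen_x"] else 0),
        copies_y=cur["wy"] + (1 if cur["seen_y"] else 0),
        x_interval=(cur["x0"], i), y_interval=(cur["y0"], j),
        column_interval=(cur["c0"], col))


def sample_instance(model: SffModel | PairHMM, rng) -> SimulatedInstance:
    """One unconstrained draw from the model."""
    hmm = model.hmm if isinstance(model, SffModel) else model
    x, y, aln, path = sample_path(hmm, rng)
    labels = [1 if hmm.is_repeat_state(s) else 0
              for s in path if hmm.is_emitting(s)]
    return SimulatedInstance(x, y, aln, path, RepeatAnnotation(labels),
                             _repeat_records(hmm, path))


def sample_dataset(model: SffModel | PairHMM, count: int, min_len: int = 200,
                   min_copies: int = 3, seed: int = 0) -> list[SimulatedInstance]:
    """Rejection-sample ``count`` instances.

    Accepts an instance when its alignment has at least ``min_len`` columns
    and every repeat event produced at least ``min_copies`` motif copies in
    each sequence (read from generation records, not re-detected).
    """
    if count < 1 or min_len < 1 or min_copies < 0:
        raise ConfigurationError("count >= 1, min_len >= 1, min_copies >= 0 required")
    rng = np.random.default_rng(seed)
    out = []
    for k in range(count):
        for attempt in range(REJECTION_CAP):
            inst = sample_instance(model, rng)
            if len(inst.alignment) < min_len:
                continue
            if all(r.copies_x >= min_copies and r.copies_y >= min_copies
                   for r in inst.repeats):
                inst.seed = seed
                out.append(inst)
                break
        else:
            raise ConfigurationError(
                f"instance {k}: rejection cap {REJECTION_CAP} exceeded "
                f"(min_len={min_len}, min_copies={min_copies})")
    return out


# ------------------------------------------------------------------ metrics
def _truth_nonrepeat_keys(truth_aln: Alignment, truth_ann: RepeatAnnotation
                          ) -> set[tuple]:
    keys = []
    i = j = 0
    for mv, lab in zip(truth_aln.moves, truth_ann.labels):
        if mv != 2:
            i += 1
        if mv != 1:
            j += 1
        if not lab:
            keys.append((int(mv), i, j))
    return set(keys)


def alignment_error_counts(pred: Alignment, truth_aln: Alignment,
                           truth_ann: RepeatAnnotation) -> tuple[int, int]:
    """(number of true non-repeat columns missed, number of such columns)."""
    if pred.n != truth_aln.n or pred.m != truth_aln.m:
        raise InputError("prediction and truth align different sequences")
    truth_keys = _truth_nonrepeat_keys(truth_aln, truth_ann)
    missed = len(truth_keys - pred.column_keys())
    return missed, len(truth_keys)


def alignment_error_rate(pred: Alignment, truth_aln: Alignment,
                         truth_ann: RepeatAnnotation) -> float | None:
    """Fraction of true non-repeat columns not present in the prediction
    (gap-position annotation included in column identity); None when the
    truth has no non-repeat columns."""
    missed, total = alignment_error_counts(pred, truth_aln, truth_ann)
    return None if total == 0 else missed / total


def _base_labels(aln: Alignment, ann: RepeatAnnotation) -> tuple[np.ndarray, np.ndarray]:
    lx = np.zeros(aln.n, dtype=bool)
    ly = np.zeros(aln.m, dtype=bool)
    i = j = 0
    for mv, lab in zip(aln.moves, ann.labels):
        if mv != 2:
            if lab:
                lx[i] = True
            i += 1
        if mv != 1:
            if lab:
                ly[j] = True
            j += 1
    return lx, ly


def repeat_base_counts(pred_aln, pred_ann, truth_aln, truth_ann):
    """(true positives, true repeat bases, predicted repeat bases), pooled
    over both sequences."""
    px, py = _base_labels(pred_aln, pred_ann)
    tx, ty = _base_labels(truth_aln, truth_ann)
    if len(px) != len(tx) or len(py) != len(ty):
        raise InputError("prediction and truth align different sequences")
    tp = int((px & tx).sum() + (py & ty).sum())
    return tp, int(tx.sum() + ty.sum()), int(px.sum() + py.sum())


def repeat_base_metrics(pred_aln, pred_ann, truth_aln, truth_ann
                        ) -> tuple[float | None, float | None]:
    """Per-base repeat (sensitivity, specificity); None on empty denominators."""
    tp, truth_pos, pred_pos = repeat_base_counts(pred_aln, pred_ann,
                                                 truth_aln, truth_ann)
    sens = None if truth_pos == 0 else tp / truth_pos
    spec = None if pred_pos == 0 else tp / pred_pos
    return sens, spec


def block_counts(pred_blocks: Sequence[Block], truth_blocks: Sequence[Block]):
    pred = {(b.x, b.y) for b in pred_blocks if b.label == 1}
    truth = {(b.x, b.y) for b in truth_blocks if b.label == 1}
    return len(pred & truth), len(truth), len(pred)

def block_metrics(pred_blocks: Sequence[Block], truth_blocks: Sequence[Block]
                  ) -> tuple[float | None, float | None]:
    """Repeat-block (sensitivity, specificity); a predicted block counts only
    on exact equality of both intervals."""
    tp, truth_n, pred_n = block_counts(pred_blocks, truth_blocks)
    sens = None if truth_n == 0 else tp / truth_n
    spec = None if pred_n == 0 else tp / pred_n
    return sens, spec


def column_distances_to_repeat(truth_aln: Alignment,
                               truth_ann: RepeatAnnotation) -> np.ndarray:
    """Distance (in columns) of every truth column to the nearest
    repeat-labeled column; the whole array is ``len+1`` when no repeat exists
    (treated as 'beyond any bin' by the caller)."""
    t = len(truth_aln)
    lab = truth_ann.labels.astype(bool)
    dist = np.full(t, t + 1, dtype=np.int64)
    last = None
    for k in range(t):
        if lab[k]:
            last = k
            dist[k] = 0
        elif last is not None:
            dist[k] = k - last
    nxt = None
    for k in range(t - 1, -1, -1):
        if lab[k]:
            nxt = k
        elif nxt is not None:
            dist[k] = min(dist[k], nxt - k)
    return dist


def error_by_distance(pred: Alignment, truth_aln: Alignment,
                      truth_ann: RepeatAnnotation, max_distance: int = 50
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-distance (missed, total) counts over true non-repeat columns.

    Bin d < max_distance holds columns at exactly distance d from the
    nearest true repeat block; the last bin pools all larger distances
    (including instances without repeats).
    """
    dist = column_distances_to_repeat(truth_aln, truth_ann)
    pred_keys = pred.column_keys()
    missed = np.zeros(max_distance + 1, dtype=np.int64)
    total = np.zeros(max_distance + 1, dtype=np.int64)
    i = j = 0
    for k, (mv, lab) in enumerate(zip(truth_aln.moves, truth_ann.labels)):
        if mv != 2:
            i += 1
        if mv != 1:
            j += 1
        if lab:
            continue
        d = min(int(dist[k]), max_distance)
        total[d] += 1
        if (int(mv), i, j) not in pred_keys:
            missed[d] += 1
    return missed, total


@dataclass
class MetricsReport:
    """Pooled accuracy of one decoder over a dataset."""

    alignment_error: float | None
    repeat_sensitivity: float | None
    repeat_specificity: float | None
    block_sensitivity: float | None
    block_specificity: float | None
    error_by_distance: tuple[np.ndarray, np.ndarray] | None = None

    def row(self) -> dict:
        def pct(v):
            return None if v is None else 100.0 * v
        return {
            "alignment_error_pct": pct(self.alignment_error),
            "repeat_sens_pct": pct(self.repeat_sensitivity),
            "repeat_spec_pct": pct(self.repeat_specificity),
            "block_sens_pct": pct(self.block_sensitivity),
            "block_spec_pct": pct(self.block_specificity),
        }


def evaluate_dataset(predictions, instances, max_distance: int = 50
                     ) -> MetricsReport:
    """Pool the four accuracy measures over (prediction, truth) pairs.

    ``predictions`` are (Alignment, RepeatAnnotation) pairs or decode
    results with ``alignment``/``annotation`` attributes, in the same order
    as ``instances``.
    """
    miss = tot = 0
    tp_b = truth_b = pred_b = 0
    tp_blk = truth_blk = pred_blk = 0
    ebd_miss = np.zeros(max_distance + 1, dtype=np.int64)
    ebd_tot = np.zeros(max_distance + 1, dtype=np.int64)
    for pred, inst in zip(predictions, instances):
        if hasattr(pred, "alignment"):
            aln, ann = pred.alignment, pred.annotation
        else:
            aln, ann = pred
        a, b = alignment_error_counts(aln, inst.alignment, inst.annotation)
        miss += a
        tot += b
        a, b, c = repeat_base_counts(aln, ann, inst.alignment, inst.annotation)
        tp_b += a
        truth_b += b
        pred_b += c
        a, b, c = block_counts(blocks_from_annotation(aln, ann),
                               blocks_from_annotation(inst.alignment,
                                                      inst.annotation))
        tp_blk += a
        truth_blk += b
        pred_blk += c
        em, et = error_by_distance(aln, inst.alignment, inst.annotation,
                                   max_distance)
        ebd_miss += em
        ebd_tot += et
    return MetricsReport(
        alignment_error=None if tot == 0 else miss / tot,
        repeat_sensitivity=None if truth_b == 0 else tp_b / truth_b,
        repeat_specificity=None if pred_b == 0 else tp_b / pred_b,
        block_sensitivity=None if truth_blk == 0 else tp_blk / truth_blk,
        block_specificity=None if pred_blk == 0 else tp_blk / pred_blk,
        error_by_distance=(ebd_miss, ebd_tot))
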