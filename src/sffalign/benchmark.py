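"""Simulation benchmark comparing decoders on data sampled from the SFF.

The protocol samples alignments from an SFF model (rejection-sampled to
length >= 200 with >= 3 motif copies per repeat in each sequence), decodes
every instance with the three-state Viterbi baseline and with SFF-based
decoders, and reports pooled alignment error rates (fraction of true
non-repeat columns missed). The headline numbers are relative error
reductions versus the baseline:

* ``reduction_marginalized`` — SFF marginalized posterior vs baseline,
* ``reduction_best_known`` — best of {marginalized, posterior, block}
  when the decoders are given the true motif library and the true repeat
  intervals (from generation records) as block candidates.

Problem sizes are deliberately desk-scale: the default is 50 alignments
over a 10-motif library (motif lengths 2-12).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment, RepeatAnnotation
from .blocks import SubstringProbTable, block_decode, candidate_blocks
from .decoding import (best_column_chain, labeled_column_posteriors,
                       marginalize_gap_columns)
from .heuristics import DEFAULT_CANDIDATE_TOL
from .hmm import viterbi_path
from .models import (SffModel, SunflowerParams, ThreeStateParams,
                     build_three_state, default_motif_library)
from .simulate import (MetricsReport, SimulatedInstance, evaluate_dataset,
                       sample_dataset)


def benchmark_model() -> SffModel:
    """The benchmark SFF: 10-motif default library, indel rates 0.005,
    motif divergence t = 0.05, default three-state core."""
    return SffModel(default_motif_library(), ThreeStateParams(),
                    SunflowerParams())


@dataclass
class BenchmarkResult:
    instances: list[SimulatedInstance]
    reports: dict[str, MetricsReport]
    predictions: dict[str, list]

    def error(self, decoder: str) -> float:
        return self.reports[decoder].alignment_error

    def reduction(self, decoder: str, baseline: str = "three_state_viterbi"
                  ) -> float:
        """Relative error reduction vs the baseline, in percent."""
        base = self.error(baseline)
        return 100.0 * (base - self.error(decoder)) / base


def _three_state_viterbi(ts_model, inst):
    path, _ = viterbi_path(ts_model, inst.x, inst.y)
    from .alignment import (alignment_from_state_path,
                            repeat_annotation_from_states)
    aln = alignment_from_state_path(ts_model, path, len(inst.x), len(inst.y))
    return aln, repeat_annotation_from_states(ts_model, path)


def _true_candidates(inst, n, m, tol):
    t_x = [r.x_interval for r in inst.repeats]
    t_y = [r.y_interval for r in inst.repeats]
    return candidate_blocks(t_x, t_y, n, m, tol)


def run_benchmark(seed: int, count: int = 50, min_len: int = 200,
                  min_copies: int = 3, sff: SffModel | None = None,
                  include_viterbi_family: bool = False,
                  include_block: bool = True,
                  tol: int = DEFAULT_CANDIDATE_TOL) -> BenchmarkResult:
    """Sample the dataset and decode it with every benchmarked decoder.

    The posterior and marginalized decoders share one labeled-posterior
    table per instance. ``include_viterbi_family`` adds the SFF Viterbi and
    three-state posterior decoders (used for ordering checks);
    ``include_block`` adds block decoding with true repeat intervals as
    candidates.
    """
    sff = sff or benchmark_model()
    data = sample_dataset(sff, count, min_len, min_copies, seed)
    ts_model = build_three_state(sff.three_state)
    preds: dict[str, list] = {k: [] for k in
                              ["three_state_viterbi", "sff_posterior",
                               "sff_marginalized"]}
    if include_block:
        preds["sff_block"] = []
    if include_viterbi_family:
        preds["sff_viterbi"] = []
        preds["three_state_posterior"] = []
    for inst in data:
        preds["three_state_viterbi"].append(_three_state_viterbi(ts_model, inst))
        table = labeled_column_posteriors(sff.hmm, inst.x, inst.y)
        preds["sff_posterior"].append(best_column_chain(table)[:2])
        preds["sff_marginalized"].append(
            best_column_chain(marginalize_gap_columns(table))[:2])
        if include_block:
            n, m = len(inst.x), len(inst.y)
            cands = _true_candidates(inst, n, m, tol)
            tables = SubstringProbTable.build(sff, inst.x, inst.y)
            r = block_decode(sff, inst.x, inst.y, cands, tables)
            preds["sff_block"].append((r.alignment, r.annotation))
        if include_viterbi_family:
            path, _ = viterbi_path(sff.hmm, inst.x, inst.y)
            from .alignment import (alignment_from_state_path,
                                    repeat_annotation_from_states)
            aln = alignment_from_state_path(sff.hmm, path,
                                            len(inst.x), len(inst.y))
            ann = repeat_annotation_from_states(sff.hmm, path)
            preds["sff_viterbi"].append((aln, ann))
            ts_table = labeled_column_posteriors(ts_model, inst.x, inst.y)
            preds["three_state_posterior"].append(
                best_column_chain(ts_table)[:2])
    reports = {k: evaluate_dataset(v, data) for k, v in preds.items()}
    return BenchmarkResult(data, reports, preds)


def known_repeat_decoders(result: BenchmarkResult) -> list[str]:
    """Decoders that receive the true motifs/intervals in the benchmark."""
    return [k for k in ("sff_marginalized", "sff_posterior", "sff_block")
            if k in result.reports]


def best_known_repeat_reduction(result: BenchmarkResult) -> tuple[str, float]:
    best = min(known_repeat_decoders(result), key=result.error)
    return best, result.reduction(best)
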