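# Methods

## Models

### Three-state pair HMM

The core model is the classical pair HMM with a match state `M` emitting
aligned symbol pairs and insert states `I_X`, `I_Y` emitting symbols aligned
to a gap. Transition parameters are expressed as `gap_open` (M→I),
`gap_extend` (I→I) and `end_prob` (every state → end), so the expected
alignment length is roughly `1/end_prob` columns. The match emission is a
joint Jukes–Cantor pair distribution: the ancestral base is drawn from the
background (uniform by default) and the descendant base diverges for time
`t`, giving `P(same) = 1/4 + (3/4) e^{-4t/3}` per base.

Defaults: `gap_open = 0.007`, `gap_extend = 0.3`, `end_prob = 0.005`, match
emission at `t = 0.3`, uniform background. These describe a
mammalian-orthologous-region regime — roughly 20% substitution divergence
with rare, moderately extended indels. They were chosen so that the
simulation benchmark (below) has the two properties reported for this class
of data: a three-state Viterbi baseline error of roughly 5% of non-repeat
columns, and baseline errors concentrated near tandem-repeat boundaries
(error within 20 columns of a repeat several-fold higher than the
far-field). A more indel-rich parameterization spreads baseline error
uniformly along the alignment and drowns the repeat-local signal that the
repeat-aware decoders target. All values are overridable per run.

### Sunflower submodels and the SFF model

A sunflower is a circular profile HMM that emits tandem copies of one
consensus motif in one sequence. For a motif of length `p` it has match
states `M_0..M_{p-1}` (emission: Jukes–Cantor divergence from the consensus
base, `t = 0.05`), insert states `I_j` (background emission, self-loop),
and two silent delete chains: `D'_0..D'_{p-2}`, enterable only from the
entry state, and `D_1..D_{p-1}`, enterable only after a match or insert in
the current copy — so no silent path can close a full period and the silent
subgraph stays acyclic. The transition wiring is a package choice (the
topology fixes the graph, not the numbers): from `M_j`, insert with
probability 0.005, delete with 0.005, advance otherwise; the wrap-around from column `p-1` to column
0 is multiplied by `copy_continue`, with the complement exiting. The copy
count is therefore geometric with mean `1/(1 - copy_continue)`.

The SFF ("sunflower field") pair HMM couples the three-state core with an
X-side and a Y-side sunflower per library motif. A silent *hub* state
follows the start state, every match emission and every repeat exit; from
the hub the model enters motif `i`'s X-side sunflower with probability
`motif_entry * prior_i`, or continues with the three-state distribution
scaled by `(1 - motif_entry)`. The X-side sunflower hands over to its
Y-side twin with probability one, so one repeat event emits the X copies
first and then the Y copies, with independent geometric copy counts on each
side — tandem arrays are modeled as orthologous but not base-aligned.
Insert states never enter repeats. With an empty library the SFF *is* the
three-state model. Defaults: `motif_entry = 0.01`, `copy_continue = 0.85`,
indel rates 0.005, `t = 0.05`.

`copy_continue = 0.85` is a benchmark-composition choice: the benchmark
keeps only instances whose repeats have at least 3 copies in both
sequences, and at 0.85 a repeat event passes that filter with probability
~0.52, so accepted datasets actually contain tandem arrays (mean ~6.7
copies, i.e. realistic short-tandem-repeat array lengths). At lower values
the filter rejects most repeat-bearing instances and the dataset degenerates
to mostly repeat-free alignments.

### TANTAN-style model

The alternative repeat model represents all repeats of period `k` with a
single order-`k` state `R_k` whose emission is conditioned on the symbol
`k` positions earlier (Jukes–Cantor conservation, time `t`); one state per
period up to `K` suffices, so the model size is `O(K)` rather than
proportional to the summed motif lengths. A prefix chain `P_1..P_K`
(background emission) covers the first motif occurrence, handing over to
`R_k` with a single shared probability `p_r`. Insertions (`I_k`,
background) lengthen the effective period by one; silent deletions `D_k`
shorten it by one; `p_ES`, `p_ER`, `p_EI` are exit probabilities from
indel, repeat and prefix states and `p_S`, `p_SE` start/extend indels. The
exit from the "init" path is taken from the prefix states rather than from
the submodel entry: a submodel pass therefore always emits at least one
symbol, which keeps the chained X-then-Y pair construction free of silent
cycles. Two copies of the submodel hang off the hub exactly like a
sunflower pair.

### SRF (sunflower repeat finder)

A single-sequence HMM: one sunflower plus a background state `B`
(self-loop 0.99, entry into the sunflower 0.005; the same row is used from
the start state and the sunflower exit so repeats may touch the sequence
ends — these two constants are exposed as arguments). Viterbi decoding
labels maximal sunflower-state runs, which become candidate repeat
intervals.

## Inference

All models compile to a flat array form and share one set of numba lattice
kernels (forward, backward, Viterbi, streamed grouped posteriors), with
log-space arithmetic throughout. Within a lattice cell, emitting states are
processed first and silent states in a topological order of the silent
subgraph; banding masks cells outside a per-row window. Viterbi
tie-breaking is deterministic: incoming edges are examined in source-state
declaration order and replaced only on strict improvement.

### Column decoders

Labeled column posteriors are computed with a checkpointed backward pass
(every ~sqrt(n)-th lattice row stored, blocks recomputed on demand — exact,
at roughly 1.5x the arithmetic) feeding a streaming forward pass, which
accumulates six per-cell groups (match / X-gap / Y-gap × repeat label).
Memory is O(sqrt(n) · m · |states|) instead of O(n · m · |states|), which
is what makes unbanded decoding of kilobase instances under the ~600-state
benchmark SFF feasible in ordinary RAM; Viterbi similarly keeps rolling
value rows and only a compact backpointer table. The three column-level criteria:

* **Viterbi** — most probable state path; alignment and repeat annotation
  read off the path.
* **Posterior** — maximum-total-posterior compatible column set, columns
  scored together with their repeat label.
* **Marginalized posterior** — gap-column posteriors first summed over the
  gap's position in the other sequence. The gain table records that its
  gap rows are already marginal sums, making the operation idempotent.

The chain DP breaks ties as match > X-gap > Y-gap, and label 0 over
label 1. Gains are added, not multiplied.

### Block decoders

The SFF collapses to a generalized pair HMM whose single repeat state `R`
emits a whole block `(x, y)` with
`Pr(x, y | R) = Σ_i prior_i · Pr(x | R_iX) · Pr(y | R_iY)`; the per-motif
substring probabilities are precomputed for all substrings by one forward
sweep per start position. Because this is an exact reparameterization, the
block model's total probability equals the SFF total (a property the test
suite checks numerically at 1e-6).

Block decoding maximizes expected gain where a candidate repeat block earns
its posterior times its number of non-gap symbols (`|x| + |y|`, both
sequences counted) and a non-repeat column earns its label-0 posterior in
the block model; a DP over cells with block jumps finds the optimal tiling.
Block Viterbi maximizes the probability of the block structure itself.
Candidate blocks are restricted to interval pairs whose endpoints fall in a
`tol`-wide window (default 10) around annotated repeat intervals, or are
empty on one side; each endpoint ranges over `tol` positions, so a
candidate set never exceeds `(100|T_X| + n)(100|T_Y| + m)` at the default
tolerance. Within a repeat block the X symbols precede the Y symbols, as
in the generative model.

## Simulation benchmark and metrics

`sample_dataset` draws instances from the SFF and keeps those with
alignment length ≥ 200 and ≥ 3 motif copies per repeat in each sequence
(copy counts come from generation records — wrap-transition crossings —
not from re-detection). The benchmark (50 instances by default, 10-motif
library with motif lengths 2–12 and length-decreasing frequency-style
priors) decodes each instance with the three-state Viterbi baseline, the
SFF posterior/marginalized decoders (one shared posterior table), and
block decoding given the true repeat intervals as candidates.

Metrics, pooled over the dataset (micro-average):

* **alignment error** — fraction of true *non-repeat* columns absent from
  the prediction; column identity includes the gap-position annotation;
* **repeat sensitivity/specificity** — per base, both sequences pooled;
* **block sensitivity/specificity** — exact interval-pair equality of
  repeat blocks;
* **error by distance** — per-column distance (in truth columns) to the
  nearest true repeat block, far distances pooled in the last bin.

Zero denominators yield absent values, never zeros.

What the simulation does *not* emulate: real tandem repeats share
evolutionary history between species (copies here are independent given
the motif), repeat arrays have partial final copies (the sunflower prefers
integer copy numbers), motif libraries are genome-scale (310k consensuses
in real use; 10 here), and real data contain non-repeat low-complexity
sequence and alignment-unrelated artifacts. Passing benchmarks therefore
demonstrate correctness of the inference machinery and the repeat-local
accuracy gains under the model's own assumptions, not field performance.

## Numerical choices

* Probability sums validate to 1e-9; DP identities (forward = backward,
  block total = SFF total) to 1e-6 relative; log-sum-exp accumulation
  skips terms more than 37 nats below the running maximum (below double
  resolution).
* Context-order states fall back to a background emission row where the
  context symbol does not exist (relevant only near sequence starts).
* Lattices are stored (i, j, state) so a cell's state vector is contiguous.
* Deterministic tie-breaks everywhere: Viterbi by state declaration order;
  column chains match > X-gap > Y-gap, label 0 first; block tilings prefer
  single columns, then blocks by earlier X start, then Y start.
* Rejection sampling caps at 10^5 attempts per instance and then raises
  with diagnostics.

## Known limitations

* Repeat submodels are entered only from the hub (post-match context), not
  from inside gap runs; a repeat immediately following a long insertion is
  reached through a match column first.
* The block decoders require the SFF factorization (X before Y inside a
  block) and do not apply to models that align repeat copies across
  sequences.
* Substring-probability tables are quadratic in sequence length per motif;
  block decoding over long sequences requires candidate restriction.
* `restrict_library` returns an intentionally unnormalized library (kept
  motifs keep their full-model entry probabilities); `restricted_sff`
  performs the bookkeeping that puts the unused mass back into the
  three-state core.
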