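# sffalign

Pairwise DNA alignment in the presence of short tandem repeats, built on
pair hidden Markov models (PHMMs) with explicit repeat submodels.

Short tandem repeats — arrays of near-identical copies of a short motif —
are a persistent source of alignment error: it is rarely clear which copies
in two related species are orthologous, and misalignments spread into the
flanking sequence. `sffalign` is for researchers in comparative genomics
who want repeat-aware pairwise alignments of genomic regions, a per-column
repeat annotation alongside the alignment, and a controlled simulation
framework for measuring what a decoding criterion actually buys.

## Models and decoders

The central model is the **SFF ("sunflower field") PHMM**: a classical
three-state PHMM (match `M`, inserts `I_X`, `I_Y`) augmented, for every
motif `i` in a library, with two *sunflower* submodels `R_{i,X}`, `R_{i,Y}`
— circular profile HMMs that emit tandem copies of the motif in one
sequence, with geometrically distributed copy number. A repeat event emits
its copies in X and then, independently, in Y: arrays are orthologous but
not base-aligned. Match states within a sunflower diverge from the
consensus under Jukes–Cantor with time `t = 0.05`; insert and delete rates
are 0.005. Also provided: a TANTAN-style model (one order-`k` state per
repeat period, size `O(K)` instead of the summed motif lengths), and the
single-sequence SRF repeat finder (sunflower + background state) for
annotating candidate repeat intervals.

Decoding is organized as maximum expected gain
`A* = argmax_A E[G(A, A_T) | X, Y]` with five gain functions:

| decoder | gain awarded for |
|---|---|
| Viterbi | the entire alignment + state path correct |
| posterior | each column correct, with its repeat label |
| marginalized posterior | as posterior, gap columns correct regardless of gap position |
| block | each non-gap symbol in every exactly-correct block |
| block Viterbi | the entire block structure correct |

The block decoders run on a generalized PHMM in which all repeat states
collapse into one block-emitting state with emission
`Pr(x,y|R) = Σ_i prior_i · Pr(x|R_{i,X}) · Pr(y|R_{i,Y})`, computed from
precomputed all-substring probability tables.

Practical machinery: banding around a guide alignment (default 30 bases),
window-wise realignment, Tandem Repeats Finder `.dat` parsing, SRF
reannotation of candidate intervals, motif-library restriction, candidate
repeat blocks with a 10-base endpoint tolerance, and three-state
realignment of predicted repeat blocks.

## Worked example

```python
from sffalign import SffModel, MotifLibrary, decode, to_gapped_strings

sff = SffModel(MotifLibrary([("AC", 0.8), ("GAT", 0.2)]))
X = "TTGCA" + "AC" * 8 + "GGTACGAT"
Y = "TTGCA" + "AC" * 5 + "GGTACGAT"

result = decode(sff.hmm, X, Y, "marginalized")
rx, ry = to_gapped_strings(result.alignment, X, Y)
labels = "".join(str(int(v)) for v in result.annotation.labels)
print(rx); print(ry); print(labels)
```

prints

```
TTGCA--A--------CACACACACACACACGGTACGAT
TTGCAAC-ACACACAC---------------GGTACGAT
000001111111111111111111111111100000000
```

Reading the output: the shared flanks `TTGCA` and `GGTACGAT` align column
by column, and the whole `AC` array is recognized as a repeat (label `1`).
Inside the labeled region the two arrays are placed against gaps rather
than against each other — the SFF deliberately does not claim orthology
between individual copies — and, crucially, the three extra copies in X do
not get smeared into the flanking alignment, which is exactly the failure
mode of a repeat-blind aligner. `realign_repeat_blocks` can re-align the
labeled region with the three-state model afterwards if base-level pairing
inside the repeat is wanted.

The same pipeline from the shell:

```sh
sffalign simulate --count 5 --seed 1 -o sim          # sample a benchmark
sffalign align pair.fa --model sff --decoder block   # align + annotate
sffalign find-repeats genome.fa ACGT                 # SRF intervals (BED)
```

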