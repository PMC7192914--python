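# Methods

This note records the modeling assumptions, parameter choices and known
limitations behind `promdesign`, in the order the pipeline runs.

## Library scaffolds

A scaffold is an ordered list of segments, each either a constant motif
(TFBS, TATA box, TSS) or a randomized spacer with a base-frequency
4-vector over (A, C, G, T).  Zero frequencies exclude bases (the post-TSS
spacer excludes G to avoid premature ATG codons); the core promoter uses a
T-rich composition (A/C/G/T = 0.30/0.12/0.12/0.46).  Coordinates are
0-based half-open; one-hot rows are ordered A, C, G, T everywhere.

Two full-size scaffolds ship with the package: the final constitutive
design (312 bp, 83% randomized, two 10-bp Rap1p sites, two Gcr1p sites,
TATA, TSS) and inducible design 4 (246 bp, 79% randomized, three
GCGTGGGCG ZEV sites with 37-bp internal spacers and an 18-bp TATA
region).  Segment lengths and compositions match the published totals;
the constant motif sequences themselves are consensus placeholders kept
in editable TSV files (`src/promdesign/data/`), because the exact
sequences are not published in a machine-readable form.  The flanking
vector context bundled with them is likewise a synthetic placeholder.
Anyone with the real sequences can drop them into the TSVs without code
changes.  The first 35 bp of each library member are fully randomized and
serve as the identifier key that links full-length consensi to short
counting reads.

`demo_scaffold()` provides structurally faithful ~90–100 bp miniatures
used in examples and desk-scale experiments, chosen so that model
training completes in about a minute per submodel on one CPU.

## Synthetic ground truth and sort simulation

Ground truth is additive on the log10 activity scale: baseline +
per-position per-base weights + motif bonuses (+ an optional pairwise
term for stress-testing).  Weights exist only at randomized positions and
only for emittable bases, are centred per position under the sampling
distribution, and are rescaled exactly so a random library member's
activity has a chosen standard deviation (default 0.2, giving a spread
resembling a measured constitutive library, roughly −0.5 to 0.6 over a
large sample).  Additivity is a deliberate choice: under it, mutagenesis
differentials have a closed form (weight differences), which makes
attribution testable to machine precision.

The sort model draws Poisson(cells_per_sequence) cells per sequence
(default 200); each cell is a uniform-bin contaminant with probability ε
(default 0.01) or normal around μ with σ (default 0.15), assigned to one
of 12 equal-width bins spanning [−0.6, 0.6].  Cells falling outside the
gates go to the nearest end bin (the gates are assumed to cover the
library's activity range; a "discard" mode exists for sensitivity
checks).  Reads carry independent per-base substitutions (default 0.5%).
What passing tests on these fixtures does **not** show: robustness to
epistasis, sequence-dependent noise (σ varying with expression), PCR
amplification bias, or optical cytometer artifacts — none of which the
generator emulates.

## Activity estimation

The estimator follows the mixture likelihood exactly as stated in the
README.  Numerical choices:

* Outer bin edges are treated as −∞/+∞ so bin probabilities sum to 1;
  a `unbounded_tails=False` switch restores finite edges (a
  conditional-on-collection likelihood) for sensitivity analysis.
* Bin probabilities are floored at 1e-300 before the log so that empty
  bins cannot produce 0 · (−∞) in the A·W product.
* The μ grid spans the bin range extended by one bin width, step 0.005;
  σ grid 0.05–0.40 step 0.01; ε grid 0–0.20 step 0.01.  All
  configurable; argmax ties break to the smallest μ, making output
  deterministic.
* Normalized counts (reads × cells/reads per bin) enter A·W as fractions
  without rounding — the likelihood is linear in counts.
* Replicates combine by the mean; pairs differing by more than 0.2 log10
  units are flagged discordant.  Sequences observed only in the extreme
  bins, or with fewer than a threshold of reads per replicate, are
  flagged and excluded from model-training tables.

At 200 cells per sequence and σ = 0.15, the information bound on a
single-replicate estimate is about 0.011 log10 units; the pipeline's
recovery experiments therefore simulate the study design as performed —
duplicate sorts combined by the replicate mean — which brings the RMSE to
about 0.008.

## Sequence reconstruction from reads

Needleman–Wunsch distance (gap 5, mismatch 1, match 0) is computed with a
vectorized row recurrence; the within-row gap chain is a running minimum
of c[k] − gap·k, which keeps the whole DP in numpy.  Clustering sorts
reads lexicographically and breaks the sorted order where adjacent reads
exceed a distance cutoff (default 10); a second pass on reversed strings
catches differences near the read start, and clusters sharing reads merge
by union-find.  For equal-length pairs the Hamming distance times the
mismatch penalty upper-bounds the alignment distance, so pairs within the
cutoff by that bound skip the DP — an optimization that cannot change the
partition.  Consensus is a per-position strict-plurality vote among reads
of the modal length; singletons, modal-length ties, and positions without
a unique winner reject the cluster.  Counting reads link to consensi by
exact 35-bp prefix match; shared prefixes exclude the affected sequences.

## Models

The engine (`promdesign.nn`) implements conv/batch-norm/ReLU/max-pool
blocks, dense layers, Huber loss and Adam in numpy (float32,
channels-last), with backward passes verified against numerical
gradients and input gradients exposed for design.  The full-scale
architecture preset (`full_architecture`) is six conv blocks of width 8 with 128
channels, two 128-unit dense layers, L2 weight 1e-4 on all kernels except
the output layer, learning rate 1e-5, Huber δ 0.15, early-stopping
patience 5, 80/10/10 split with nine validation folds.  The desk-scale
preset used in tests keeps the block structure with two blocks of 16
channels, learning rate 3e-3 and batch 64, which converges in tens of
epochs.  The output layer is initialized near zero so initial predictions
start at the target mean — without this, small models spend hundreds of
Adam steps rescaling their output range before learning anything.

Sequences embed in ≥ 25 bp of vector context per side; shorter libraries
get longer pads so all encoded inputs share one length.  Shift
augmentation displaces the padded frame by 0–7 positions during training
(validation and prediction use shift 0).  Desk-scale experiments disable
the shift (encoder `shift_max=0`): at 16 channels the invariance it
demands measurably slows learning of position-specific effects, and the
augmentation path is exercised by its own tests instead.  Constitutive
examples under a two-output head supervise both outputs (the masked-loss
alternative is a config switch).  Mean−SD merging uses the population SD
(divisor k).

## Design

Screening samples library members and keeps those whose merged score
clears the threshold.  Evolution mutates only randomized positions
(replacement bases drawn from the segment composition), passes the
highest-scoring variant to the next cycle (literally — even if worse than
its parent; a hill-climb mode is a config switch), and decays the
per-cycle mutation count 8 → 4 → 2 → 1 over quartiles of the cycle
budget (100 variants/cycle, 200 cycles by default).  Gradient ascent
maintains a continuous relaxation of the one-hot input, adds
step_size × gradient of the merged objective at entries whose sampling
frequency is nonzero (so excluded bases can never round in, and constant
columns stay frozen), rounds by per-column argmax, and scores the rounded
sequence each step.  The default step size is 1.0: input gradients of the
reduced ensemble are ~0.02 per entry, and a much smaller step cannot flip
an argmax within the step cap.  Constraints (GC window, BsaI) are checked
at acceptance; budgets are iteration counts, not wall-clock, for
determinism.  Threshold adjustment moves in 0.05 increments: downward to
the first threshold at which a full set can be produced, upward to the
last achievable one.  The activation-ratio objective is the difference of
merged log10 activities (a delogged-ratio alternative would change only
monotone scaling).

## Mutagenesis

Score differential = mutant − original (negative means predicted loss);
position score = the greatest predicted loss among the three mutants.
Block finding applies the select-fraction quantile to the per-position
most-negative differentials of randomizable positions and reports runs of
at least 6 strictly below it — the most-negative tail, which is where
loss-of-function motifs live.  TA repeats are whole-unit runs (length in
bases, even), located by regex; each sequence contributes its longest
repeat and a baseline from 5′-spacer positions outside any qualifying
repeat.  The ZEV site-extension analysis classifies the 4-mer after each
site occurrence as GCTA or not and compares median differentials over
those four positions.  Mutagenesis predictions use shift 0 and the same
merge mode as the design objective.

## Problem sizes

The test suite and acceptance script use: 1,000 sequences × 2 replicates
× 200 cells for activity recovery; 500 sequences × 10 reads for
reconstruction; 5,000 sequences and a 3-submodel reduced ensemble for
learnability; design sets of 8–12 sequences; 16 sequences × 3L mutants
for mutagenesis.  These sizes were chosen so each stage finishes in
seconds to a couple of minutes on one CPU while leaving every statistical
conclusion comfortably clear of its threshold.

## Known limitations

* The bundled scaffolds' constant motifs and vector flanks are
  placeholders at the published lengths, not the published sequences.
* The ground truth is additive by default; the CNN's advantage over
  linear models on real (epistatic) data is not demonstrated by these
  fixtures.
* The desk-scale presets demonstrate the machinery, not the full-scale
  accuracy; reproducing published-scale numbers requires the deposited
  data and the full-scale preset at far larger compute.
* Per-sequence σ, Bayesian intervals, and GPU execution are out of scope.
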