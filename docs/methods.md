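# Methods

`mutenc` is a desk-scale implementation of biophysics-pretrained protein
sequence encoders: a transformer is first trained to predict many simulated
biophysical score terms for variant sequences of a base protein, then its
layers are reused as the backbone of a single-output model finetuned on
(small) experimental sequence-function datasets. The package covers the full
workflow — simulation, preprocessing, pretraining, finetuning, extrapolation
benchmarking, epistasis analysis and simulated-annealing sequence design —
with every stage testable against known ground truth.

## The model

The encoder is a pre-layer-norm transformer over the 20-letter amino-acid
alphabet plus a pad token (21-token vocabulary). There is no absolute
positional encoding; position enters only through learned relative position
embeddings (RPE) added to attention keys and values, one head-dim-wide vector
per relative-distance bucket, per layer, shared across heads:

* **1D RPE** — bucket = signed sequence offset `j − i`, clipped to ±8
  (17 buckets). Used for multi-protein ("global") models.
* **3D RPE** — the structure is reduced to a residue contact graph with an
  edge whenever Cβ atoms (Cα for glycine or residues missing Cβ) are within
  8 Å, inclusive; bucket = shortest-path length in that graph clipped at 3
  (0 self, 1 contact, 2 second shell, 3 everything else, including
  disconnected pairs). Used for single-protein ("local") models.

After the encoder: a final layer norm, mean pooling over residues, a ReLU
fully-connected layer, and a linear multi-task output. Presets:

| preset    | embed | layers | heads | ff   | pooled hidden | parameters |
|-----------|-------|--------|-------|------|---------------|------------|
| local     | 256   | 3      | 4     | 1024 | 256           | 2,456,631  |
| global    | 512   | 6      | 8     | 2048 | 512           | 19,230,007 |
| global-xl | 512   | 16     | 8     | 2048 | 512           | 50,775,607 |

Parameter totals are exact trainable counts for 55 output tasks and follow
directly from the table's hyperparameters; the global preset's total is
usually quoted as "~20M" and the enlarged one as "~50M".

Target models keep the backbone, insert dropout 0.5, and add a linear
1-output head — after the final fully-connected layer for local backbones,
directly after pooling for global ones. The source model's multi-task output
layer is not part of the target model.

The network, AdamW, schedules and backpropagation are implemented on a small
reverse-mode autodiff core over numpy float64 (`mutenc.nn`). Every operation's
gradient is finite-difference checked in the test suite; the restricted
two-operand einsum used by the RPE attention rejects contractions its
gradient rule cannot handle. Weight initialization is fan-based uniform for
linear layers and normal(0, 0.02) for embedding/RPE tables, always drawn from
an explicitly passed seeded generator; a module-level default generator
deliberately does not exist.

## The synthetic simulator

The simulator substitutes a known, seeded energy model for a molecular
mechanics pipeline so that every downstream claim can be validated against
ground truth. On the structure's contact graph,

    E(seq) = Σ_i [ h(a_i) + b(a_i)·deg_i ] + Σ_{(i,j)∈edges} J(a_i, a_j)

with per-amino-acid field energies `h`, burial weights `b` scaled by contact
degree, and a symmetric 20×20 pair coupling `J`. The three summands form a
component vector; each of the 60 cataloged score terms is a fixed seeded
mixture of the components plus optional Gaussian observation noise (default
sd 0.05 per term), and `total_score` is the plain component sum. Seventeen
optional binding terms are computed the same way from interface-restricted
parameters `(g, J_b)` over a designated interface residue set. Three catalog
terms (`dslf_fa13`, `linear_chainbreak`, `overlap_chainbreak`) are emitted
identically zero, `filter_total_score` duplicates `total_score`, and
`res_count_all` is the constant sequence length — so the preprocessing
exclusion rules operate on columns that genuinely carry no variant signal.

Two properties make the simulator a useful oracle. With `J ≡ 0` every variant
effect is exactly additive, so pairwise epistasis is identically zero; with
`J ≠ 0` epistasis can arise only at contacting position pairs. Both are
asserted in the tests.

Toy structures: `chain` style places residues 5 Å apart on a line (a path
contact graph); `globule` style packs residues uniformly in a ball whose
radius scales as n^(1/3) at one residue per ~300 Å³ with a 3.8 Å clash
distance. The density was fixed once after measuring contact-graph degrees
over 20 seeds, giving protein-like mean degrees (about 3–5, within the 2–10
band) for lengths 20–100.

Synthetic experimental datasets score sampled variants by latent fitness
−E(seq), optionally squashed through a logistic link centered on the
wild-type latent value (mimicking a saturating assay), add Gaussian assay
noise (default sd 0.1), normalize so the wild type's realized score is
exactly 0, and round to 7 decimals.

What the simulator does **not** emulate: real energy-function physics,
heavy-tailed score distributions beyond the explicit fault injectors,
position-specific burial beyond contact degree, correlated assay error, or
epistasis between non-contacting residues. Passing tests therefore show that
the machinery behaves as specified under a known landscape — not that the
models reach any particular accuracy on real proteins.

## Preprocessing

Attribute tables are cleaned in a fixed order: drop rows with any NaN
attribute; deduplicate per (base protein, variant), keeping one seeded-random
row; then, per base-protein group, remove rows whose `total_score` modified
z-score exceeds 6.5, where

    s_i = |x_i − median(x)| / MAD,   MAD = median_j |x_j − median(x)|.

The absolute deviation is used in the numerator: a signed numerator could
never flag low-side outliers and would be inconsistent with MAD itself. No
0.6745 consistency constant is applied. Groups with MAD = 0 (e.g. constant
scores) skip outlier removal with a warning. Cleaning is idempotent on the
seeded tables used in the tests; a second pass removes nothing.

Standardization is per (base protein, term) with means and standard
deviations computed on training rows only; held-out rows are transformed
with the training statistics. Constant terms are centered only.

Experimental tables are normalized by removing stop-codon variants,
converting indexing to 0-based, log-transforming when the input is not
already on a log scale, subtracting the wild-type score and rounding to 7
decimals.

## Training

Pretraining minimizes the sum over score terms of per-term batch MSE with
AdamW (lr 1e-3, betas (0.9, 0.999), eps 1e-8, weight decay 0.01), linear
warmup over 2% of steps, gradient-norm clipping at 0.5, and 30 epochs by
default. Batches are always homogeneous in base protein so a single
relative-distance map serves the whole batch; an `accum_chunks` option
reproduces a larger effective batch by gradient accumulation on one process
(chunked and unchunked steps agree to float tolerance when dropout is off).
Training refuses tables whose per-group training statistics are far from
mean 0 / sd 1.

Finetuning is dual-phase: 250 epochs head-only on a frozen backbone (lr
1e-3), then 250 epochs of everything (lr 1e-4), each phase with 1% warmup
and cosine decay to 0, batch 128, weight decay 0.1, clipping 0.5. During
phase 1 the frozen backbone runs in evaluation mode and its features are
computed once and cached (the 0.5 dropout between backbone and head stays
active); the backbone weights are bit-identical before and after phase 1.
Model selection takes the lowest-validation-loss epoch across both phases
when the validation set has at least 32 rows (local convention; 128 for
global models, configurable), otherwise the final weights — small validation
sets make per-epoch selection noise dominate. Feature extraction is the
closed-form alternative: ridge regression (alpha 1.0, Cholesky solver) on the
cached features, written back into the linear head so the model's own forward
pass reproduces the ridge predictions. A randomly initialized baseline is the
same finetuning run from a fresh backbone, not a separate code path.

## Splits and metrics

See the `evaluate` module docstring for the four extrapolation
constructions. Decisions worth noting: variants scoring exactly 0 (= wild
type) belong to neither pool of the score split; datasets above 50,000 rows
are resampled down to the cap before position/mutation/score splits; the
regime split samples a 10% test set from the double-mutant pool while the
other splits use their full test pool (an asymmetry kept as published);
top-k selection breaks ties by stable index order. Metrics are Spearman rank
correlation (NaN with a warning when the truth is constant) and recall of
the top-k (default 100) true variants among the top-k predicted.

Epistasis: w(S) = score(S) − score(WT); E(S) = w(S) − Σ_{m∈S} w(m), zero by
convention for singles; positional epistasis is the mean |E| over double
mutants at each position pair.

## Sequence design

Simulated annealing maximizes any sequence-scoring function over variants
with exactly `n_mutations` substitutions. Temperatures follow a log-spaced
schedule from 10 down to 10⁻² inclusive. Proposals draw how many mutations to
redraw from a Poisson (rate 1 by default — small steps dominate near
convergence; clipped to [1, n_mutations]), keep a random subset of current
mutations and refill without replacement from the constraint-legal mutation
set, so every visited state is feasible. Moves with Δ ≥ 0 are always accepted
(Δ = 0 included, since exp(0/T) = 1); worse moves with probability
exp(Δ/T). Constraints are sets of (position, mutant) pairs: observed designs
reuse only the allowed set, unobserved designs exclude it.

Each run reports both its final and best-seen state; clustering consumes
final states by default (one solution per run), switchable to best-seen.
Designs are clustered by complete-linkage agglomeration under the BLOSUM62
quadratic-form dissimilarity d(x,y) = Σ_i (B(x_i,x_i)+B(y_i,y_i))/2 −
B(x_i,y_i), chosen because it is nonnegative and zero exactly for identical
sequences (a shifted raw −similarity is available behind a flag). Clusters
below 100 members (or a fraction, via `min_cluster_frac`) are dropped; each
survivor is represented by its member with the lowest mean within-cluster
distance; selection starts from the largest cluster and greedily adds the
representative with the largest mean distance to those already chosen.

## Problem sizes used in the tests

The heavy properties run on a length-20 globular toy protein: pretraining
uses 2,000 noiseless simulated variants (up to 5 substitutions), a mini
encoder (embed 32, 2 layers, 4 heads, ff 64, pooled hidden 32) and the full
30-epoch schedule. The transfer property finetunes on 64 noiseless examples
and evaluates Spearman on 500 held-out variants over 5 seeds against an
identically finetuned randomly initialized twin; the attention property
compares 3D- and 1D-RPE twins pretrained on the coupled (J ≠ 0) simulator.
These sizes are the package's chosen study conditions; all seeds are fixed.

## Known limitations

* The simulator's three-component structure makes the 55 score terms highly
  mutually redundant; multi-task pretraining here is easier than on real
  heterogeneous energy terms.
* Variable-length batching relies on the single-base-protein batch rule;
  padded mixed-length batches are not masked in attention.
* The autodiff core is float64 and single-threaded numpy; it is sized for
  desk-scale models (millions of parameters, short sequences), not GPU-scale
  pretraining.
* Checkpoints guarantee reload-equivalence on one platform, not bitwise
  portability across BLAS builds.
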