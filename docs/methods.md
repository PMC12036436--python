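# Methods

## Model

We treat development as a stochastic process over a discrete sequence of
time layers.  Each observed cell j carries a configuration
C_j = (x_j, ẋ_j): its expression vector and its RNA velocity (an input;
the package does not estimate velocity from spliced/unspliced counts).
A trajectory γ = (C₀, …, C_T) visits one cell (later: one token) per
layer.  The central identity is that the action of a trajectory is its
surprise under a trajectory distribution p_θ,

    𝓐_θ(γ) = −log p_θ(γ),

so the expected action over an ensemble equals the Shannon entropy of
the trajectory distribution, and minimizing the mean action over
observed trajectories is exactly autoregressive maximum-likelihood
training.  All entropies and actions are reported in nats; the
Boltzmann constant is set to 1 throughout (none of the downstream
quantities use physical units).

## Trajectory construction

**Configurations.**  Expression is standardized gene-wise over the
pooled table; genes with zero variance are dropped with a warning.  The
standardized matrix is projected onto its top `n_pcs` principal axes
(default 30, standard scRNA practice).  Velocity is divided by the same
gene scales and projected onto the same basis — it is a direction, so
the centering offset is not subtracted — then scaled by
`velocity_weight` (default 1; 0 gives expression-only configurations)
and concatenated.  Projection is an explicit matrix product against the
fitted components rather than the SVD's row scores: the product maps
bitwise-identical cells to bitwise-identical configurations, which the
quantizer relies on to merge duplicate states.

**Candidates and kernels.**  For each cell in layer t the candidate
next states are its k nearest layer-(t+1) cells by Euclidean distance
in configuration space (default k = 30; ties at the k-th distance break
by ascending cell index).  Restricting candidates to the next layer
matches the multipartite structure of the trajectory graph.  Transition
probabilities are a softmax over Pearson correlations of configuration
vectors,

    p(j→k) = exp(corr(C_j, C_k)) / Σ_{l∈𝓝_j} exp(corr(C_j, C_l));

a constant configuration vector has undefined correlation and is scored
0 with a warning.  Pearson on the full concatenated configuration is
the most literal reading of a correlation between generalized
coordinates; `velocity_weight` exposes how strongly velocity shapes the
similarity, and expression-only analysis is available by setting it to
zero.

**Memory.**  The non-Markovian kernel scores candidate k by
Σ_{m=0}^{L−1} λ^m corr(C_{t−1−m}, C_k) over the last L visited states,
most recent first, with λ⁰ = 1 by convention (so λ = 0 and L = 1 both
reduce exactly to the Markov kernel); terms reaching before the start
of the trajectory are skipped.  Sampling starts from a uniformly drawn
layer-0 cell — the distribution of progenitor states is not modeled, so
uniform is the maximum-entropy default — and walks the kernel to the
final layer.

## Tokenization

Configuration space is quantized **per time layer** with
centroid-based vector quantization: seeded k-means++ initialization
followed by Lloyd iterations (at most 100, usually converging in a
handful), nearest-centroid ties broken to the lowest token id, empty
tokens dropped.  Lloyd is implemented in the package rather than taken
from a library because the determinism contract (seeded init, explicit
tie-break, duplicate handling, empty-drop) is part of the interface.
When the requested per-layer size reaches the layer size, every cell
becomes its own token (zero quantization error).  Quantizing per layer
means a token identifies both a state-space region and a time step,
which keeps "correct temporal order" well defined for generated
sequences; a token's cell type is the majority type of its members.

## Autoregressive models

`TabularARModel` stores empirical conditional frequencies for context
orders 1..L with suffix backoff down to the position-wise marginal; for
any context seen in training its distribution equals count ratios
exactly, which makes it the reference model for testing (it provably
minimizes the mean action on its own training sample).

`TransformerARModel` is a decoder-only causal transformer implemented
directly on numpy arrays with hand-written backpropagation and Adam.
The input at each position is the sum of a token embedding, a cell-type
embedding (the token's majority type; a dedicated row serves the
begin-of-sequence token) and a learned position embedding.  Defaults
are deliberately desk-scale — 2 pre-norm blocks, width 64, 4 heads,
GELU MLPs, learning rate 1e-2, batch 64 — because the vocabularies this
package targets are tens to a few hundred tokens and sequences are tens
of steps; at that scale numpy training is bit-reproducible for a given
seed on one thread and takes seconds.  Training holds out a seeded
fraction of trajectories (default 20%), early-stops on the held-out
loss with patience 25 and restores the best parameters.  The empty
prefix is handled by prepending the learned begin-of-sequence token.

Model quality is tracked as loss (mean action per trajectory), accuracy
and coverage.  Accuracy is reported as two rates, because "predicting
the right next state" is ambiguous between temporal and identity
correctness: layer-order accuracy (the argmax token belongs to the
correct time layer) and exact-token accuracy.  Coverage is the fraction
of evaluation tokens that appear anywhere in a generated ensemble,
order-independent.  Over a temperature sweep coverage rises and exact
accuracy falls — the exploration–exploitation trade-off the entropy
metric quantifies per step.

**Generation** uses nucleus sampling with temperature → top-k → top-p
filter order (the common convention; the three parameters are
order-ambiguous in isolation), ties at either truncation boundary
breaking by ascending token id, and survivors renormalized with removed
entries exactly zero.

## Metrics

**Normalized entropy.**  H_norm(t) = −Σ p log p / log N_t over the
model's next-token distribution at step t, temperature-scaled,
*restricted to layer-t tokens* and renormalized; N_t is the number of
layer-t tokens.  The restriction is required for the normalization by
log N_t to bound the quantity in [0, 1]; single-token layers return 0
by convention.  Profiles average over sampled trajectories (default
100 samples) per temperature, optionally grouped by the cell type of
the current token.  Entropy is computed from the model distribution;
an empirical-frequency mode is available by fitting the tabular model
to a raw ensemble first.

**Balanced Forman curvature.**  The trajectory graph has one node per
visited token and an undirected edge per consecutive pair with
traversal multiplicity.  For an edge (i, j):

    Ric(i,j) = 2/d_i + 2/d_j − 2 + 2T_ij/max(d_i,d_j) + T_ij/min(d_i,d_j)
               + (S_i + S_j)/(γ_max · max(d_i,d_j)),

with Ric := 0 when min(d_i, d_j) = 1 and the last term defined as 0
when γ_max = 0.  T_ij counts triangles on the edge (identically zero
here: the graph is bipartite by layer parity); S_i counts neighbors of
i completing a diagonal-free 4-cycle through the edge, and γ_max is the
maximal number of such 4-cycles traversing a common node — the precise
set-based definitions from the graph-curvature literature, validated
exactly against a brute-force enumerator on random graphs.  Because
degree can mean either distinct neighbors or total trajectory
traversals, both modes are surfaced (`simple`, the standard choice and
default, and `multiplicity`); cycle combinatorics always live on the
simple graph, since the curvature is an undirected simple-graph
quantity.  Node curvature is the degree-normalized sum of incident edge
curvatures, multiplicity-weighted in multiplicity mode.

**Entropy production.**  σ(γ) = log p_θ(γ) − log p_θ(γ̃) for the full
reversal, and σ_{i,j}(γ) uses the trajectory with positions i..j
(inclusive) reversed in place.  Its ensemble expectation equals the KL
divergence between forward and reversed sequence distributions (two
independent code paths in the package, cross-checked in tests), hence
is non-negative; it vanishes under detailed balance.  Reversed
sequences place tokens at the wrong time steps; the transformer scores
any token sequence (token embeddings are position-independent inputs),
while the tabular model may assign such sequences probability zero —
those cells become +inf sentinels, and the entropy-production map
reports the count of infinite cells per (start, length) rather than
imputing.  For map-style irreversibility analyses the trained
transformer is therefore the natural scoring model.

## Synthetic data

The generator emulates the layered structure of time-stamped scRNA
datasets: T+1 layers of `cells_per_layer` cells, lineage latent means
following a seeded Gaussian random walk per gene (step scale
`drift_scale`), designed branch points, and an optional bottleneck.
Cell expression is the lineage mean plus i.i.d. Gaussian noise
(`noise_sd`, default 0.05 — small relative to the unit drift so lineage
structure dominates but states are not degenerate); velocity is the
displacement to the lineage's next-layer mean plus the same noise, so
velocity is informative about the true direction (the final layer uses
one virtual continuation step).  Ground truth records each cell's
lineage, a true parent in the previous layer, the designed branch
probabilities and the bottleneck location.

Two design choices deserve note:

* **Branches diverge at the branch layer.**  Children take independent
  random-walk steps from the parent's previous-layer mean, rather than
  sharing the parent's state at the branch layer.  If labels appear at
  the branch layer while states are still shared, the first post-branch
  transition is unrecoverable from configurations in principle; with
  immediate divergence, lineage recovery from noise-free data is
  well-posed, and the package's recovery checks (sampled steps follow
  the true lineage >95% at zero noise) pass by construction of the
  kernel rather than by labeling accident.
* **Bottleneck = exact collapse for the non-surviving lineages.**  At
  the bottleneck layer, `surviving_fraction` of lineages keep their own
  latent mean; the rest copy the first survivor's mean exactly at that
  layer (the walk continues from the collapsed value, so lineages
  re-diversify afterwards).  Exact collapse, not shrinkage toward a
  centroid: shrinkage leaves distinct states that per-layer
  quantization re-separates, and the entropy valley would vanish.  With
  full collapse on noise-free data the layer quantizes to a single
  token and the low-temperature entropy profile attains a strict
  interior minimum there — the qualitative signature a real
  developmental bottleneck leaves in this metric.

What the generator does **not** model: transcription/splicing kinetics,
sequencing depth, dropout, or any noise structure beyond additive
Gaussian.  Passing tests therefore demonstrate that the pipeline's
machinery recovers designed structure under its own assumptions, not
that it is robust to the artifacts of real scRNA data.

## Numerical choices and degenerate inputs

* All randomness derives from one master seed via named CRC-32
  substreams, so any stage can be re-run in isolation reproducibly;
  identical config + inputs give byte-identical outputs.
* Probability-vector checks use 1e-9; kernel row-stochasticity 1e-12.
* Softmaxes subtract the max before exponentiating; temperature is
  applied in log space.
* Zero-probability steps give −inf log-likelihood (+inf action) rather
  than raising; exhaustive enumerations (exact trajectory entropy,
  expected entropy production) walk the model's support and guard at
  10⁶ sequences.
* Time labels in input metadata are rank-mapped to a contiguous 0-based
  range, with the mapping recorded in the run manifest (how real
  collection times are binned into discrete steps is a convention, not
  something the data dictates); a strict mode instead rejects
  non-contiguous integer labels, naming the gap.
* MTX inputs use `.mtx.rows` / `.mtx.cols` plain-text sidecars; the
  velocity matrix must match the expression dialect and shape.

## Problem sizes

The shipped examples and tests run at deliberately small scale —
hundreds of cells, 30 genes, 5–7 layers, vocabularies of a few tokens
per layer, a width-64 two-block transformer — chosen so the full suite
completes in well under a minute of compute while every scientific
property (oracle equivalence, reduction identities, parameter recovery,
bottleneck/bridge/irreversibility signatures) is still exercised
end to end.  All sizes are configuration parameters; nothing in the
implementation assumes them.

## Limitations

* Velocity is consumed as given; no estimation, smoothing or
  denoising.
* The entropy profile presupposes layer-specific tokens; it is not
  defined for vocabularies whose Voronoi cells span layers.
* The tabular model cannot score sequences with tokens at unseen
  positions (see entropy production above).
* Whether the correlation kernel should see expression only or the full
  (x, ẋ) pair is genuinely open; both are supported and the default
  (full pair) is a choice, not a claim.
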